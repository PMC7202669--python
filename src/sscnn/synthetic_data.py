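"""Synthetic corpora: sequences, labels, disorder masks, profiles, metadata.

The generator emits format-faithful fixtures for every input the rest of the
package consumes, with a controllable amount of learnable signal:

* 8-state label strings are drawn from a run-length process — run labels are
  sampled i.i.d. with weights ``w_l ~ f_l / m_l`` and run lengths are
  geometric with per-label means ``m_l``, which makes the expected label
  fractions equal the configured targets (defaults follow the label
  composition of a large nonredundant PDB snapshot: H 34.1%, E 22.3%,
  C 19.4%, T 11.1%, S 8.2%, G 3.9%, B 1.1%);
* pi-helix labels (I) are produced only at the ends of alpha-helix runs,
  where they occur in real structures, at a rate tuned to their ~0.02%
  natural frequency;
* residue identities are drawn from label-conditional amino-acid
  distributions whose sharpness is the ``signal_strength`` knob (0 = no
  signal: sequence independent of labels);
* disorder is placed at chain termini at a configurable rate (6.5% of
  residues by default, matching the fraction of residues without
  coordinates in the PDB);
* PSSM and HHM fixtures carry the same label-conditional bias plus noise,
  in the exact ASCII layouts the feature parsers read.

The generator plants signal at the emission level only: there is no real
physics (no pairing between strands, no hydrophobic periodicity), so a model
trained on these corpora demonstrates that the learning machinery works, not
that it predicts real proteins.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np

from .dataset_protocol import ChainMetadataRecord
from .features import (
    HHM_NORM,
    HHMProfile,
    PSSMProfile,
    write_hhm,
    write_pssm,
)
from .labels import STANDARD_AA, LabeledChain, SSDisRecord, write_ss_dis

__all__ = [
    "GeneratorConfig",
    "ProfileSet",
    "SyntheticCorpus",
    "MetadataFixture",
    "simulate_chain",
    "simulate_profiles",
    "simulate_corpus",
    "simulate_metadata",
]

#: Target stationary label percentages (pi helix handled contextually).
DEFAULT_LABEL_FREQS = {
    "H": 34.1, "E": 22.3, "C": 19.4, "T": 11.1, "S": 8.2, "G": 3.9, "B": 1.1,
}

#: Mean run lengths per label; helices and strands form long runs, bridges
#: are single residues by definition.
DEFAULT_RUN_LENGTHS = {
    "H": 9.0, "E": 5.0, "C": 3.0, "T": 2.5, "S": 1.8, "G": 3.2, "B": 1.0,
}

#: Label-favoured amino acids used to plant sequence signal.
FAVORED_AA = {
    "H": "AELMQK", "I": "AELMQK",
    "E": "VIFYW", "B": "VIFYW",
    "C": "GND", "T": "PST", "S": "RHC", "G": "AGP",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus generator (defaults follow the label
    composition of real structure corpora; ``signal_strength`` 0 produces a
    null corpus)."""

    n_chains: int = 80
    min_length: int = 40
    max_length: int = 400
    label_freqs: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_FREQS))
    run_lengths: dict = field(default_factory=lambda: dict(DEFAULT_RUN_LENGTHS))
    pi_helix_rate: float = 0.002
    signal_strength: float = 2.0
    disorder_rate: float = 0.065
    profile_noise: float = 1.0
    pssm_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("invalid chain length range")
        if self.signal_strength < 0:
            raise ValueError("signal strength must be >= 0")
        if not 0 <= self.disorder_rate < 1:
            raise ValueError("disorder rate must be in [0, 1)")

    def emission_matrix(self) -> dict:
        """p(amino acid | label) for the 8 states, rows summing to 1."""
        out = {}
        for label in "HBEGITSC":
            boost = np.ones(20)
            for aa in FAVORED_AA.get(label, ""):
                boost[STANDARD_AA.index(aa)] = np.exp(self.signal_strength)
            out[label] = boost / boost.sum()
        return out


def _sample_labels(config: GeneratorConfig, length: int,
                   rng: np.random.Generator) -> str:
    freqs = config.label_freqs
    labels = list(freqs)
    w = np.array([freqs[l] / config.run_lengths[l] for l in labels])
    w /= w.sum()
    out: list = []
    while len(out) < length:
        label = labels[rng.choice(len(labels), p=w)]
        run = rng.geometric(1.0 / config.run_lengths[label])
        out.extend(label * run)
    s = "".join(out[:length])

    # pi helices appear only as the final turn of a long alpha helix
    if config.pi_helix_rate > 0:
        chars = list(s)
        i = 0
        while i < length:
            if chars[i] == "H":
                j = i
                while j < length and chars[j] == "H":
                    j += 1
                if j - i >= 7 and rng.random() < config.pi_helix_rate:
                    for k in range(j - 3, j):
                        chars[k] = "I"
                i = j
            else:
                i += 1
        s = "".join(chars)
    return s


def simulate_chain(config: GeneratorConfig, seed: int,
                   pdb_id: str = "0001", chain_id: str = "A") -> tuple:
    """One synthetic chain.

    Returns ``(chain, disorder)``: a :class:`LabeledChain` whose ``labels8``
    already carries 'X' at disordered positions, and the raw disorder mask.
    Disorder is termini-biased — it never interrupts a run mid-chain.
    """
    rng = np.random.default_rng(seed)
    length = int(rng.integers(config.min_length, config.max_length + 1))
    hidden = _sample_labels(config, length, rng)

    emissions = config.emission_matrix()
    aa_idx = [rng.choice(20, p=emissions[l]) for l in hidden]
    sequence = "".join(STANDARD_AA[i] for i in aa_idx)

    n_dis = rng.binomial(length, config.disorder_rate)
    n_dis = min(n_dis, length - 1)  # keep at least one ordered residue
    n_front = rng.binomial(n_dis, 0.5)
    disorder = "X" * n_front + "-" * (length - n_dis) + "X" * (n_dis - n_front)
    labels8 = "".join(
        "X" if d == "X" else l for l, d in zip(hidden, disorder)
    )
    chain = LabeledChain(pdb_id=pdb_id, chain_id=chain_id,
                         sequence=sequence, labels8=labels8)
    return chain, disorder


def simulate_profiles(chain: LabeledChain, config: GeneratorConfig,
                      seed: int) -> "ProfileSet":
    """Format-faithful PSSM (rounds 1 and 2) and HHM fixtures for a chain.

    Log-odds scores are biased toward each position's label-typical residues
    plus integer noise; the round-2 profile is a position-smoothed copy of
    round 1, emulating profile broadening on the second search iteration.
    HHM emissions encode the same distributions in the -1000*log2(p)
    convention with '*' for vanishing probabilities.
    """
    rng = np.random.default_rng(seed)
    emissions = config.emission_matrix()
    bg = np.full(20, 1.0 / 20.0)
    L = len(chain)

    probs = np.empty((L, 20))
    for i, label in enumerate(chain.labels8):
        probs[i] = emissions[label] if label != "X" else bg

    logodds = config.pssm_scale * np.log2(probs / bg)
    noise = rng.normal(0.0, config.profile_noise, size=(L, 20))
    scores1 = np.rint(np.clip(logodds + noise, -19, 19))
    # second round: neighbourhood smoothing of the first-round scores
    padded = np.vstack([scores1[:1], scores1, scores1[-1:]])
    scores2 = np.rint((padded[:-2] + padded[1:-1] + padded[2:]) / 3.0)

    pssm1 = PSSMProfile(scores=scores1, sequence=chain.sequence, round_index=1)
    pssm2 = PSSMProfile(scores=scores2, sequence=chain.sequence, round_index=2)

    # HHM: noisy emission probabilities in the -1000*log2(p) encoding
    alpha = 50.0 * np.maximum(probs, 1e-6)
    noisy = np.vstack([rng.dirichlet(a) for a in alpha])
    with np.errstate(divide="ignore"):
        emit_vals = np.where(noisy > 2**-90, -1000.0 * np.log2(noisy), HHM_NORM)
    emit_vals = np.minimum(np.rint(emit_vals), HHM_NORM)
    trans = np.tile(
        np.array([0.0, 5000.0, 5000.0, 0.0, HHM_NORM, 0.0, HHM_NORM,
                  1500.0, 0.0, 0.0]),
        (L, 1),
    )
    values = np.hstack([emit_vals, trans]) / HHM_NORM
    hhm = HHMProfile(values=values, sequence=chain.sequence)
    return ProfileSet(pssm1=pssm1, pssm2=pssm2, hhm=hhm)


@dataclass
class ProfileSet:
    pssm1: PSSMProfile
    pssm2: PSSMProfile
    hhm: HHMProfile

    def as_texts(self) -> tuple:
        return (write_pssm(self.pssm1), write_pssm(self.pssm2),
                write_hhm(self.hhm))


@dataclass
class SyntheticCorpus:
    """A complete synthetic data set with all cross-referenced artifacts."""

    config: GeneratorConfig
    chains: list
    records: list           # SSDisRecord per chain
    profiles: dict          # chain key -> ProfileSet

    @property
    def ss_dis_text(self) -> str:
        return write_ss_dis(self.records)

    @property
    def fasta_text(self) -> str:
        out = []
        for rec in self.records:
            out.append(f">{rec.pdb_id}:{rec.chain_id}")
            for i in range(0, len(rec.sequence), 60):
                out.append(rec.sequence[i:i + 60])
        return "\n".join(out) + "\n"

    def write(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "corpus.ssdis").write_text(self.ss_dis_text)
        (directory / "corpus.fasta").write_text(self.fasta_text)
        for key, pset in self.profiles.items():
            stem = key.replace(":", "_")
            p1, p2, hh = pset.as_texts()
            (directory / f"{stem}.mtx-1").write_text(p1)
            (directory / f"{stem}.mtx-2").write_text(p2)
            (directory / f"{stem}.hhm").write_text(hh)


def _record_from_chain(chain: LabeledChain, disorder: str) -> SSDisRecord:
    """Reconstruct the raw ss_dis triple that combines back into ``chain``."""
    secstr = "".join(
        " " if l in ("C", "X") else l for l in chain.labels8
    )
    return SSDisRecord(pdb_id=chain.pdb_id, chain_id=chain.chain_id,
                       sequence=chain.sequence, secstr=secstr,
                       disorder=disorder)


def simulate_corpus(config: GeneratorConfig, seed: int) -> SyntheticCorpus:
    """Generate a deterministic corpus; same (config, seed) => same bytes."""
    root = np.random.default_rng(seed)
    chain_seeds = root.integers(0, 2**31 - 1, size=config.n_chains)
    profile_seeds = root.integers(0, 2**31 - 1, size=config.n_chains)
    chains, records, profiles = [], [], {}
    for i in range(config.n_chains):
        pdb_id = f"{i + 1:04d}"
        chain, disorder = simulate_chain(config, int(chain_seeds[i]),
                                         pdb_id=pdb_id, chain_id="A")
        chains.append(chain)
        records.append(_record_from_chain(chain, disorder))
        profiles[chain.key] = simulate_profiles(chain, config,
                                                int(profile_seeds[i]))
    return SyntheticCorpus(config=config, chains=chains, records=records,
                           profiles=profiles)


# ---------------------------------------------------------------------------
# Metadata / protocol fixtures
# ---------------------------------------------------------------------------

@dataclass
class MetadataFixture:
    """Chain metadata plus an injected identity matrix and ECOD fixture.

    Constructed to exercise every protocol branch: exact duplicates,
    near-duplicates at controlled identities (including the 25.0 boundary),
    boundary-quality records, CA-only models, chains on both sides of the
    date cutoff, and an ECOD table covering each lookup-cascade branch.
    """

    records: list
    identity: dict          # frozenset({key_a, key_b}) -> percent identity
    ecod_text: str
    cutoff_date: datetime.date
    same_sequence_index: dict


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(STANDARD_AA[i] for i in rng.integers(0, 20, size=length))


def simulate_metadata(config: GeneratorConfig, seed: int) -> MetadataFixture:
    rng = np.random.default_rng(seed)
    cutoff = datetime.date(2018, 1, 1)
    records: list = []
    identity: dict = {}

    def add(pdb, chain, seq, date, res, rfree=None, rwork=None,
            ca_only=False, n_coords=None):
        records.append(ChainMetadataRecord(
            pdb_id=pdb, chain_id=chain, sequence=seq,
            release_date=date, resolution=res, r_free=rfree, r_work=rwork,
            ca_only=ca_only,
            n_coords=n_coords if n_coords is not None else len(seq)))
        return records[-1]

    # a pool of unrelated reference chains released before the cutoff
    n_ref = 8
    ref_seqs = [_random_sequence(rng, int(rng.integers(60, 200)))
                for _ in range(n_ref)]
    for i, seq in enumerate(ref_seqs):
        add(f"r{i:03d}", "A", seq, datetime.date(2016, 3, 1 + i),
            1.8, rfree=0.20)

    # candidates after the cutoff: clean keepers
    n_cand = 6
    cand_seqs = [_random_sequence(rng, int(rng.integers(60, 200)))
                 for _ in range(n_cand)]
    cands = [add(f"c{i:03d}", "A", seq,
                 datetime.date(2018, 2, 1 + i), 1.9, rfree=0.22)
             for i, seq in enumerate(cand_seqs)]

    # exact duplicates of a candidate, at different quality
    dup = add("d001", "A", cand_seqs[0], datetime.date(2018, 3, 1), 1.5,
              rfree=0.19)
    add("d002", "A", cand_seqs[0], datetime.date(2018, 3, 2), 2.0, rfree=0.24)

    # near-duplicate above the identity threshold to a reference chain
    near = add("n001", "A", _random_sequence(rng, 120),
               datetime.date(2018, 4, 1), 1.7, rfree=0.21)
    identity[frozenset((near.key, records[0].key))] = 26.0
    # boundary case: identity exactly 25.0 to a reference -> kept
    edge = add("n002", "A", _random_sequence(rng, 130),
               datetime.date(2018, 4, 2), 1.7, rfree=0.21)
    identity[frozenset((edge.key, records[1].key))] = 25.0
    # intra-set similar trio (mutually > threshold); best resolution survives
    trio = [add(f"t{i:03d}", "A", _random_sequence(rng, 110),
                datetime.date(2018, 5, 1 + i), res, rfree=0.22)
            for i, res in enumerate((1.6, 1.9, 2.1))]
    for a in trio:
        for b in trio:
            if a.key < b.key:
                identity[frozenset((a.key, b.key))] = 40.0

    # quality boundary records
    add("q001", "A", _random_sequence(rng, 40), datetime.date(2018, 6, 1),
        2.2, rfree=0.25)                                   # boundary: kept
    add("q002", "A", _random_sequence(rng, 39), datetime.date(2018, 6, 2),
        1.5, rfree=0.20)                                   # too short
    add("q003", "A", _random_sequence(rng, 80), datetime.date(2018, 6, 3),
        2.3, rfree=0.20)                                   # resolution fail
    add("q004", "A", _random_sequence(rng, 80), datetime.date(2018, 6, 4),
        2.0, rwork=0.21)                                   # eff. R 0.26 fail
    add("q005", "A", _random_sequence(rng, 80), datetime.date(2018, 6, 5),
        2.0, rfree=0.20, ca_only=True)                     # CA-only fail
    add("q006", "A", _random_sequence(rng, 80), datetime.date(2018, 6, 6),
        None)                                              # no resolution

    # ECOD fixture: cover each lookup-cascade branch
    ecod_rows = []

    def ecod_row(uid, pdb, chain, f_id):
        ecod_rows.append(
            f"{uid}\te{uid}\tF\t{f_id}\t{pdb}\t{chain}\tA:1-100\t1-100\t"
            f"Q00000\talpha\txgroup\thgroup\ttgroup\tfgroup\tNOT_DOMAIN_ASSEMBLY\tNO_LIGANDS"
        )

    # direct hits for reference chains (two share group 1.1 with cands[1])
    ecod_row(1, "r000", "A", "1.1.1.1")
    ecod_row(2, "r001", "A", "2004.1.1.2")
    # cands[0] found directly, same X.H as r000 -> removed by homology filter
    ecod_row(3, "c000", "A", "1.1.2.5")
    # cands[1]: no direct record; sibling chain B of same entry, unique group
    ecod_row(4, "c001", "B", "3001.1.1.1")
    # cands[2]: resolved via a different PDB entry carrying the same sequence
    ecod_row(5, "x001", "A", "4007.2.1.1")
    # cands[3..]: no ECOD path at all -> unresolved

    same_seq_index = {
        cand_seqs[1]: [("c001", "A"), ("c001", "B")],
        cand_seqs[2]: [("c002", "A"), ("x001", "A")],
    }
    for rec in records:
        same_seq_index.setdefault(rec.sequence, []).append(
            (rec.pdb_id, rec.chain_id))

    header = "#uid\tecod_domain_id\tmanual_rep\tf_id\tpdb\tchain\tpdb_range\tseqid_range\tunp_acc\tarch_name\tx_name\th_name\tt_name\tf_name\tasm_status\tligand"
    ecod_text = header + "\n" + "\n".join(ecod_rows) + "\n"

    return MetadataFixture(records=records, identity=identity,
                           ecod_text=ecod_text, cutoff_date=cutoff,
                           same_sequence_index=same_seq_index)
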