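"""Unbiased training/test set construction over chain-metadata tables.

The protocol that produces an unbiased benchmark test set from PDB-style
chain metadata is a deterministic sequence of filters:

1. split chains by release date at a cutoff (test candidates on/after);
2. collapse identical sequences, keeping the best-quality structure;
3. quality filters — resolution <= 2.2 A, effective free R <= 0.25 (R-work +
   0.05 when free R is absent), length >= 40, no C-alpha-only models;
4. remove any candidate with more than 25% sequence identity to *any*
   reference chain, under *either* of two identity definitions;
5. enforce the same 25% cutoff within the set, keeping the best-quality
   member of each similar group;
6. optionally remove candidates sharing an ECOD X.H homology group with any
   training chain.

Identity backends are pluggable.  The built-in backend computes a global
alignment (BLOSUM62, affine gaps) via Biopython and supports the two
denominator conventions used by common alignment tools: identities divided
by the shortest sequence length, or by the number of aligned (non-gap)
columns.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ChainMetadataRecord",
    "IdentityBackend",
    "AlignmentIdentityBackend",
    "MatrixIdentityBackend",
    "ECODTable",
    "builtin_identity",
    "date_split",
    "dedup_identical",
    "quality_filter",
    "cross_set_identity_filter",
    "intra_set_identity_reduce",
    "train_valid_split",
    "ecod_lookup",
    "ecod_homology_filter",
    "quality_sort_key",
]

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 25.0
DEFAULT_MAX_RESOLUTION = 2.2
DEFAULT_MAX_R = 0.25
DEFAULT_MIN_LENGTH = 40


@dataclass(frozen=True)
class ChainMetadataRecord:
    """Quality, date and provenance metadata for one protein chain."""

    pdb_id: str
    chain_id: str
    sequence: str
    release_date: datetime.date | None = None
    resolution: float | None = None
    r_free: float | None = None
    r_work: float | None = None
    ca_only: bool = False
    n_coords: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.key}: empty sequence")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError(f"{self.key}: non-positive resolution")

    @property
    def key(self) -> str:
        return f"{self.pdb_id}:{self.chain_id}"

    @property
    def effective_r(self) -> float | None:
        """Free R if deposited, else R-work + 0.05, else None."""
        if self.r_free is not None:
            return self.r_free
        if self.r_work is not None:
            return self.r_work + 0.05
        return None


def quality_sort_key(rec: ChainMetadataRecord) -> tuple:
    """Preference order: best resolution, then best effective R, then most
    residues with coordinates, then (pdb_id, chain_id) for determinism."""
    inf = float("inf")
    res = rec.resolution if rec.resolution is not None else inf
    r = rec.effective_r if rec.effective_r is not None else inf
    ncoord = rec.n_coords if rec.n_coords is not None else 0
    return (res, r, -ncoord, rec.pdb_id, rec.chain_id)


# ---------------------------------------------------------------------------
# Identity backends
# ---------------------------------------------------------------------------

class IdentityBackend:
    """Strategy computing percent identity for a pair of records."""

    name: str = "abstract"

    def identity(self, a: ChainMetadataRecord, b: ChainMetadataRecord) -> float:
        raise NotImplementedError


class AlignmentIdentityBackend(IdentityBackend):
    """Global-alignment identity with a configurable denominator.

    ``definition="shortest"`` divides the identity count by the shorter
    sequence length (symmetric); ``definition="aligned"`` divides by the
    number of aligned residue pairs, excluding gap positions.
    """

    def __init__(self, definition: str = "shortest",
                 open_gap: float = -11.0, extend_gap: float = -1.0):
        if definition not in ("shortest", "aligned"):
            raise ValueError(f"unknown identity definition {definition!r}")
        self.definition = definition
        self.name = f"alignment-{definition}"
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "global"
        self._aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self._aligner.open_gap_score = open_gap
        self._aligner.extend_gap_score = extend_gap

    def identity_from_sequences(self, seq_a: str, seq_b: str) -> float:
        aln = self._aligner.align(seq_a, seq_b)[0]
        identities = aligned = 0
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            aligned += a1 - a0
            identities += sum(
                1 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]) if x == y
            )
        if self.definition == "shortest":
            denom = min(len(seq_a), len(seq_b))
        else:
            denom = aligned
        if denom == 0:
            return 0.0
        return 100.0 * identities / denom

    def identity(self, a, b):
        return self.identity_from_sequences(a.sequence, b.sequence)


class MatrixIdentityBackend(IdentityBackend):
    """Identity lookup from an injected symmetric pairwise matrix.

    ``matrix`` maps frozenset({key_a, key_b}) (or (key, key) diagonal) to a
    percent identity; unknown pairs default to 0 unless ``default`` says
    otherwise.  Used to drive protocol tests with exactly known identities.
    """

    name = "matrix"

    def __init__(self, matrix: dict, default: float = 0.0):
        self.matrix = matrix
        self.default = default

    def identity(self, a, b):
        if a.key == b.key or a.sequence == b.sequence:
            return 100.0
        return float(self.matrix.get(frozenset((a.key, b.key)), self.default))


def builtin_identity(seq_a: str, seq_b: str, definition: str = "shortest") -> float:
    """Percent identity between two sequences under one denominator rule."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    return AlignmentIdentityBackend(definition).identity_from_sequences(seq_a, seq_b)


# ---------------------------------------------------------------------------
# Protocol filters
# ---------------------------------------------------------------------------

def date_split(records: Iterable[ChainMetadataRecord],
               cutoff_date: datetime.date) -> tuple:
    """(before, after): released strictly before the cutoff vs on/after."""
    before, after = [], []
    for rec in records:
        if rec.release_date is None:
            raise ValueError(f"{rec.key}: missing release date")
        (before if rec.release_date < cutoff_date else after).append(rec)
    return before, after


def dedup_identical(records: Iterable[ChainMetadataRecord]) -> tuple:
    """Collapse records with identical sequences.

    Returns ``(survivors, links)`` where each surviving record is the
    best-quality structure of its sequence and ``links`` maps the survivor
    key to the full list of records sharing the sequence.
    """
    by_seq: dict = {}
    order: list = []
    for rec in records:
        if rec.sequence not in by_seq:
            by_seq[rec.sequence] = []
            order.append(rec.sequence)
        by_seq[rec.sequence].append(rec)
    survivors, links = [], {}
    for seq in order:
        group = sorted(by_seq[seq], key=quality_sort_key)
        survivors.append(group[0])
        links[group[0].key] = group
    return survivors, links


def quality_filter(records: Iterable[ChainMetadataRecord],
                   max_resolution: float = DEFAULT_MAX_RESOLUTION,
                   max_r: float = DEFAULT_MAX_R,
                   min_length: int = DEFAULT_MIN_LENGTH) -> list:
    """Keep crystal-quality chains: resolution and effective R within the
    (inclusive) thresholds, length >= min_length, not C-alpha-only."""
    kept = []
    for rec in records:
        if rec.ca_only:
            logger.info("quality_filter: %s rejected (CA-only model)", rec.key)
            continue
        if rec.resolution is None:
            logger.info("quality_filter: %s rejected (no resolution)", rec.key)
            continue
        if rec.resolution > max_resolution:
            continue
        r = rec.effective_r
        if r is None or r > max_r:
            continue
        if len(rec.sequence) < min_length:
            continue
        kept.append(rec)
    return kept


def _exceeds(a: ChainMetadataRecord, b: ChainMetadataRecord,
             backends: list, threshold: float, on_error: str) -> bool:
    """True if any backend reports identity strictly above the threshold."""
    for backend in backends:
        try:
            ident = backend.identity(a, b)
        except Exception as exc:  # noqa: BLE001 - backend failures are data
            logger.warning("identity backend %s failed on (%s, %s): %s",
                           getattr(backend, "name", "?"), a.key, b.key, exc)
            if on_error == "reject":
                return True
            continue
        if ident > threshold:
            return True
    return False


def cross_set_identity_filter(candidates: Iterable[ChainMetadataRecord],
                              reference_set: Iterable[ChainMetadataRecord],
                              backends: list,
                              threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                              on_error: str = "ignore") -> list:
    """Drop candidates more than ``threshold``% identical to any reference
    chain under *any* backend (strictly-greater boundary)."""
    if not backends:
        raise ValueError("at least one identity backend required")
    reference = list(reference_set)
    kept = []
    for cand in candidates:
        if any(_exceeds(cand, ref, backends, threshold, on_error)
               for ref in reference):
            continue
        kept.append(cand)
    return kept


def intra_set_identity_reduce(records: Iterable[ChainMetadataRecord],
                              backends: list,
                              threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                              on_error: str = "ignore") -> list:
    """Greedy non-redundant reduction within a set.

    Chains are visited in quality order (best first); a chain is kept iff it
    is not more than ``threshold``% identical to any already-kept chain.
    The result is independent of the input ordering.
    """
    if not backends:
        raise ValueError("at least one identity backend required")
    ordered = sorted(records, key=quality_sort_key)
    kept: list = []
    for rec in ordered:
        if any(_exceeds(rec, other, backends, threshold, on_error)
               for other in kept):
            continue
        kept.append(rec)
    return kept


def train_valid_split(records: list, ratio: float = 0.9, seed: int = 0) -> tuple:
    """Random chain-level split; ``ratio`` is the training fraction."""
    import numpy as np

    records = list(records)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(ratio * len(records)))
    train = [records[i] for i in order[:n_train]]
    valid = [records[i] for i in order[n_train:]]
    return train, valid


# ---------------------------------------------------------------------------
# Metadata table I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["pdb_id", "chain_id", "sequence", "release_date",
                "resolution", "r_free", "r_work", "ca_only", "n_coords"]


def write_metadata_tsv(records: Iterable[ChainMetadataRecord]) -> str:
    """Serialize records to the tab-separated chain-metadata layout."""
    import pandas as pd

    rows = []
    for rec in records:
        rows.append({
            "pdb_id": rec.pdb_id,
            "chain_id": rec.chain_id,
            "sequence": rec.sequence,
            "release_date": rec.release_date.isoformat() if rec.release_date else "",
            "resolution": "" if rec.resolution is None else rec.resolution,
            "r_free": "" if rec.r_free is None else rec.r_free,
            "r_work": "" if rec.r_work is None else rec.r_work,
            "ca_only": int(rec.ca_only),
            "n_coords": "" if rec.n_coords is None else rec.n_coords,
        })
    return pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(sep="\t", index=False)


def read_metadata_tsv(text: str) -> list:
    """Parse the tab-separated chain-metadata layout into records."""
    import io

    import pandas as pd

    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"pdb_id": str,
                                                         "chain_id": str})
    records = []
    for row in df.itertuples(index=False):
        def opt(v, cast=float):
            return None if pd.isna(v) or v == "" else cast(v)

        records.append(ChainMetadataRecord(
            pdb_id=str(row.pdb_id),
            chain_id=str(row.chain_id),
            sequence=str(row.sequence),
            release_date=(datetime.date.fromisoformat(str(row.release_date))
                          if not pd.isna(row.release_date) else None),
            resolution=opt(row.resolution),
            r_free=opt(row.r_free),
            r_work=opt(row.r_work),
            ca_only=bool(int(row.ca_only)) if not pd.isna(row.ca_only) else False,
            n_coords=opt(row.n_coords, int),
        ))
    return records


# ---------------------------------------------------------------------------
# ECOD homology
# ---------------------------------------------------------------------------

@dataclass
class ECODTable:
    """Mapping from (pdb_id, chain_id) to the chain's X.H group set.

    Built from the tab-separated ``ecod.develop*.domains.txt`` layout, where
    column 4 (``f_id``) encodes the X.H.T.F hierarchy; the X.H group is its
    first two dot-separated components.
    """

    groups: dict = field(default_factory=dict)

    @classmethod
    def from_text(cls, text: str) -> "ECODTable":
        groups: dict = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"ECOD row has {len(cols)} columns, expected >= 6")
            f_id, pdb, chain = cols[3], cols[4], cols[5]
            xh = ".".join(f_id.split(".")[:2])
            groups.setdefault((pdb.lower(), chain), set()).add(xh)
        return cls(groups=groups)

    def get(self, pdb_id: str, chain_id: str) -> set | None:
        return self.groups.get((pdb_id.lower(), chain_id))


def ecod_lookup(record: ChainMetadataRecord, ecod: ECODTable,
                same_sequence_index: dict | None = None) -> tuple:
    """Resolve a chain's X.H groups through the lookup cascade.

    1. exact (pdb_id, chain_id);
    2. a chain with the same sequence in the same PDB entry;
    3. a chain with the same sequence in a different PDB entry.

    Returns ``(groups, status)`` with status in {"direct", "same_pdb",
    "other_pdb", "unresolved"}.  ``same_sequence_index`` maps a sequence to
    the (pdb_id, chain_id) pairs known to carry it.
    """
    direct = ecod.get(record.pdb_id, record.chain_id)
    if direct is not None:
        return direct, "direct"
    siblings = (same_sequence_index or {}).get(record.sequence, [])
    for pdb, chain in siblings:
        if pdb.lower() == record.pdb_id.lower() and chain != record.chain_id:
            groups = ecod.get(pdb, chain)
            if groups is not None:
                return groups, "same_pdb"
    for pdb, chain in siblings:
        if pdb.lower() != record.pdb_id.lower():
            groups = ecod.get(pdb, chain)
            if groups is not None:
                return groups, "other_pdb"
    return set(), "unresolved"


def ecod_homology_filter(candidates: Iterable[ChainMetadataRecord],
                         training_set: Iterable[ChainMetadataRecord],
                         ecod: ECODTable,
                         same_sequence_index: dict | None = None) -> list:
    """Keep candidates sharing no X.H group with any training chain.

    Candidates whose lookup is unresolved are excluded (logged) rather than
    passed through, since their homology status is unknown.
    """
    training_groups: set = set()
    for rec in training_set:
        groups, _ = ecod_lookup(rec, ecod, same_sequence_index)
        training_groups |= groups
    kept = []
    for rec in candidates:
        groups, status = ecod_lookup(rec, ecod, same_sequence_index)
        if status == "unresolved":
            logger.info("ecod_homology_filter: %s unresolved, excluded", rec.key)
            continue
        if groups & training_groups:
            continue
        kept.append(rec)
    return kept
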