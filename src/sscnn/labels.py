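"""Secondary-structure label handling.

Ground-truth labels come from DSSP assignments distributed in the PDB
``ss_dis.txt`` dialect: for every chain, three equal-length strings — the
amino-acid sequence, the DSSP string (``H B E G I T S`` plus space for
unassigned coil), and a disorder mask (``-`` ordered, ``X`` missing
coordinates).  This module parses and writes that dialect, combines DSSP and
disorder strings into a single 9-letter label string (8 DSSP states, ``C``
for coil, ``X`` for disordered), reduces the 8-state alphabet to the smaller
prediction alphabets used in the field, and computes corpus label statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, TextIO

__all__ = [
    "STANDARD_AA",
    "DSSP_LETTERS",
    "LABELS8",
    "SSDisRecord",
    "LabeledChain",
    "AlphabetScheme",
    "SCHEMES",
    "get_scheme",
    "LabelStatistics",
    "SSDisFormatError",
    "parse_ss_dis",
    "write_ss_dis",
    "combine_dssp_disorder",
    "reduce_alphabet",
    "label_statistics",
    "classify_G_context",
]

#: The 20 standard amino acids, alphabetically by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Letters a DSSP string may contain (space = unassigned / coil).
DSSP_LETTERS = set("HBEGITS ")

#: The combined 8-state alphabet plus 'X' for residues without coordinates.
LABELS8 = "HBEGITSCX"

# Non-standard one-letter codes that have no standard analog; mapped to 'X'
# on ingest so the featurizer's 22-symbol alphabet is total.
_NONSTANDARD_AA = set("BZUOJ")


class SSDisFormatError(ValueError):
    """Malformed record in an ss_dis-dialect stream."""


@dataclass(frozen=True)
class SSDisRecord:
    """One chain's raw sequence / DSSP / disorder triple."""

    pdb_id: str
    chain_id: str
    sequence: str
    secstr: str
    disorder: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SSDisFormatError(f"{self.key}: empty sequence")
        if not (len(self.sequence) == len(self.secstr) == len(self.disorder)):
            raise SSDisFormatError(
                f"{self.key}: section lengths differ "
                f"(sequence {len(self.sequence)}, secstr {len(self.secstr)}, "
                f"disorder {len(self.disorder)})"
            )

    @property
    def key(self) -> str:
        return f"{self.pdb_id}:{self.chain_id}"


@dataclass(frozen=True)
class LabeledChain:
    """A chain with its combined 8-state + disorder label string.

    ``labels8`` uses the 8 DSSP letters with spaces resolved to ``C`` and
    disordered residues marked ``X``.  Positions labeled ``X`` are excluded
    from all training and testing counts but still contribute sequence (and
    profile) context to neighbouring windows.
    """

    pdb_id: str
    chain_id: str
    sequence: str
    labels8: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.labels8):
            raise ValueError(
                f"{self.key}: sequence and labels8 lengths differ"
            )
        bad = set(self.labels8) - set(LABELS8)
        if bad:
            raise ValueError(f"{self.key}: invalid labels {sorted(bad)!r}")

    @property
    def key(self) -> str:
        return f"{self.pdb_id}:{self.chain_id}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlphabetScheme:
    """A total mapping from the 8 DSSP letters onto a reduced alphabet.

    ``mapping`` covers all of ``HBEGITSC``; ``X`` always maps to ``X`` and is
    never part of a scheme's letter set.
    """

    name: str
    mapping: dict = field(hash=False)

    def __post_init__(self) -> None:
        missing = set("HBEGITSC") - set(self.mapping)
        if missing:
            raise ValueError(f"scheme {self.name}: no rule for {sorted(missing)}")

    @property
    def letters(self) -> tuple:
        """Target letters, in first-appearance order of H,E,C,T,G,S,B,I."""
        seen: list = []
        for src in "HECTGSBI":
            dst = self.mapping[src]
            if dst not in seen:
                seen.append(dst)
        return tuple(seen)

    @property
    def n_labels(self) -> int:
        return len(self.letters)

    def __call__(self, labels: str) -> str:
        return reduce_alphabet(labels, self)


def _scheme(name: str, rules: dict) -> AlphabetScheme:
    mapping = {}
    for sources, target in rules.items():
        for s in sources:
            mapping[s] = target
    return AlphabetScheme(name=name, mapping=mapping)


#: The six label alphabets.  ``rule1_3`` and ``rule2_3`` are the two
#: conventions found in the literature for collapsing DSSP to {H, E, C};
#: ``new5``/``new4``/``new3`` fold the low-signal bend and bridge states
#: (and progressively 3_10 helix and turn) into coil while sending the rare
#: pi helix to H.
SCHEMES: dict = {
    "dssp8": _scheme("dssp8", {"H": "H", "B": "B", "E": "E", "G": "G",
                               "I": "I", "T": "T", "S": "S", "C": "C"}),
    "rule1_3": _scheme("rule1_3", {"HGI": "H", "EB": "E", "CST": "C"}),
    "rule2_3": _scheme("rule2_3", {"H": "H", "E": "E", "GIBTSC": "C"}),
    "new5": _scheme("new5", {"CSB": "C", "HI": "H", "E": "E", "T": "T", "G": "G"}),
    "new4": _scheme("new4", {"CSBG": "C", "HI": "H", "E": "E", "T": "T"}),
    "new3": _scheme("new3", {"CSBGT": "C", "HI": "H", "E": "E"}),
}


def get_scheme(name: str) -> AlphabetScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise KeyError(
            f"unknown alphabet scheme {name!r}; choose from {sorted(SCHEMES)}"
        ) from None


@dataclass(frozen=True)
class LabelStatistics:
    """Counts and percentages per label over a corpus, excluding 'X'."""

    scheme: str
    counts: dict
    total_labeled: int

    @property
    def fractions(self) -> dict:
        """Percent of labeled residues per label (full precision)."""
        return {l: 100.0 * c / self.total_labeled for l, c in self.counts.items()}

    def fraction(self, label: str, ndigits: int | None = None) -> float:
        f = self.fractions[label]
        return f if ndigits is None else round(f, ndigits)


# ---------------------------------------------------------------------------
# ss_dis dialect I/O
# ---------------------------------------------------------------------------

_SECTION_ORDER = ("sequence", "secstr", "disorder")


def parse_ss_dis(stream: TextIO | str) -> list:
    """Parse an ss_dis-dialect stream into :class:`SSDisRecord` objects.

    Each chain contributes three blocks ``>ID:CHAIN:sequence``,
    ``>ID:CHAIN:secstr`` and ``>ID:CHAIN:disorder``, each followed by one or
    more wrapped content lines.  Whitespace inside secstr lines is meaningful
    and preserved verbatim; only the line terminator is stripped.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    # Collect (pdb, chain) -> {section: text} in file order.
    order: list = []
    sections: dict = {}
    current: tuple | None = None
    for lineno, line in enumerate(lines, 1):
        if line.startswith(">"):
            try:
                pdb_id, chain_id, section = line[1:].split(":")
            except ValueError:
                raise SSDisFormatError(
                    f"line {lineno}: malformed header {line!r}"
                ) from None
            if section not in _SECTION_ORDER:
                raise SSDisFormatError(
                    f"line {lineno}: unknown section {section!r}"
                )
            key = (pdb_id, chain_id)
            if key not in sections:
                sections[key] = {}
                order.append(key)
            if section in sections[key]:
                raise SSDisFormatError(
                    f"{pdb_id}:{chain_id}: duplicate section {section!r}"
                )
            sections[key][section] = []
            current = (key, section)
        elif current is not None:
            key, section = current
            sections[key][section].append(line)
        elif line.strip():
            raise SSDisFormatError(f"line {lineno}: content before any header")

    records = []
    for pdb_id, chain_id in order:
        got = sections[(pdb_id, chain_id)]
        missing = [s for s in _SECTION_ORDER if s not in got]
        if missing:
            raise SSDisFormatError(
                f"{pdb_id}:{chain_id}: missing section(s) {missing}"
            )
        records.append(
            SSDisRecord(
                pdb_id=pdb_id,
                chain_id=chain_id,
                sequence="".join(got["sequence"]),
                secstr="".join(got["secstr"]),
                disorder="".join(got["disorder"]),
            )
        )
    return records


def write_ss_dis(records: Iterable[SSDisRecord], width: int = 75) -> str:
    """Serialize records back to the ss_dis dialect (inverse of parsing)."""
    out = []
    for rec in records:
        for section in _SECTION_ORDER:
            text = getattr(rec, section if section != "secstr" else "secstr")
            out.append(f">{rec.pdb_id}:{rec.chain_id}:{section}")
            for i in range(0, len(text), width):
                out.append(text[i:i + width])
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Label construction and reduction
# ---------------------------------------------------------------------------

def clean_sequence(sequence: str) -> str:
    """Map non-standard residue letters (B, Z, U, O, J) to 'X'."""
    return "".join("X" if c in _NONSTANDARD_AA else c for c in sequence.upper())


def combine_dssp_disorder(record: SSDisRecord) -> LabeledChain:
    """Combine a DSSP string and disorder mask into one label string.

    A disordered position (``X`` in the mask) becomes ``X`` regardless of the
    DSSP letter; an ordered position keeps its DSSP letter, with spaces
    (unassigned) resolved to coil ``C``.
    """
    out = []
    for i, (ss, dis) in enumerate(zip(record.secstr, record.disorder)):
        if dis == "X":
            out.append("X")
        elif dis == "-":
            if ss == " ":
                out.append("C")
            elif ss in DSSP_LETTERS:
                out.append(ss)
            else:
                raise SSDisFormatError(
                    f"{record.key}: invalid DSSP letter {ss!r} at position {i}"
                )
        else:
            raise SSDisFormatError(
                f"{record.key}: invalid disorder character {dis!r} at position {i}"
            )
    return LabeledChain(
        pdb_id=record.pdb_id,
        chain_id=record.chain_id,
        sequence=clean_sequence(record.sequence),
        labels8="".join(out),
    )


def reduce_alphabet(labels8: str, scheme: AlphabetScheme | str) -> str:
    """Apply an alphabet scheme letter-by-letter; 'X' is preserved verbatim."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    out = []
    for c in labels8:
        if c == "X":
            out.append("X")
        else:
            try:
                out.append(scheme.mapping[c])
            except KeyError:
                raise ValueError(
                    f"unknown source label {c!r} for scheme {scheme.name}"
                ) from None
    return "".join(out)


def label_statistics(
    chains: Iterable[LabeledChain], scheme: AlphabetScheme | str = "dssp8"
) -> LabelStatistics:
    """Count reduced labels over a corpus, excluding disordered positions."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    counts: Counter = Counter()
    for chain in chains:
        reduced = reduce_alphabet(chain.labels8, scheme)
        counts.update(c for c in reduced if c != "X")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no assignable labels: every residue is disordered")
    # report every scheme letter, including zero-count ones
    full = {l: counts.get(l, 0) for l in scheme.letters}
    return LabelStatistics(scheme=scheme.name, counts=full, total_labeled=total)


def distribution_table(chains: Iterable[LabeledChain],
                       schemes: tuple = ("dssp8", "rule1_3", "rule2_3",
                                         "new4", "new5")) -> str:
    """Tab-separated per-chain label table (sequence plus every reduced
    label string), the layout used to distribute ready-made data sets."""
    header = ["pdb_id", "chain_id", "sequence"] + list(schemes)
    rows = ["\t".join(header)]
    for chain in chains:
        cells = [chain.pdb_id, chain.chain_id, chain.sequence]
        cells += [reduce_alphabet(chain.labels8, s) for s in schemes]
        rows.append("\t".join(cells))
    return "\n".join(rows) + "\n"


def statistics_report(stats: LabelStatistics) -> str:
    """Tab-separated label-statistics report (one-decimal percentages)."""
    rows = ["label\tcount\tpercent"]
    for label, count in sorted(stats.counts.items(),
                               key=lambda kv: -kv[1]):
        rows.append(f"{label}\t{count}\t{stats.fraction(label, 1)}")
    rows.append(f"total\t{stats.total_labeled}\t100.0")
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# 3_10 helix context subclasses
# ---------------------------------------------------------------------------

#: G-run subclasses: runs abutting an alpha helix, isolated runs of length
#: three (the common case, resembling consecutive beta turns), and isolated
#: runs of length four or more.
G_SUBCLASSES = ("abut_H", "isolated_GGG", "isolated_GGGG_plus", "none")


def classify_G_context(labels8: str) -> list:
    """Classify each position's G run; non-G positions get ``"none"``.

    A maximal run of ``G`` adjacent (on either side) to an ``H`` residue is
    ``abut_H``; otherwise isolated runs of length >= 4 are
    ``isolated_GGGG_plus`` and shorter isolated runs are ``isolated_GGG``.
    """
    n = len(labels8)
    out = ["none"] * n
    i = 0
    while i < n:
        if labels8[i] != "G":
            i += 1
            continue
        j = i
        while j < n and labels8[j] == "G":
            j += 1
        left = labels8[i - 1] if i > 0 else ""
        right = labels8[j] if j < n else ""
        if left == "H" or right == "H":
            kind = "abut_H"
        elif j - i >= 4:
            kind = "isolated_GGGG_plus"
        else:
            # isolated runs of length 1-3 all go to the loop-like class
            kind = "isolated_GGG"
        for k in range(i, j):
            out[k] = kind
        i = j
    return out
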