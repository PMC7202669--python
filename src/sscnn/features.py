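"""Profile parsing and window featurization.

Each residue to be predicted is represented by a (29, 92) matrix: a window of
29 sequence positions (center residue +/- 14) with 92 features per position —

* 22 one-hot amino-acid indicators: the 20 standard residues alphabetically,
  ``X`` (non-standard residue inside the chain), and ``?`` (position outside
  the chain);
* 20 PSI-BLAST log-odds scores from the round-1 profile;
* 20 PSI-BLAST log-odds scores from the round-2 profile;
* 30 HMM parameters (20 emissions, 7 transitions, 3 diversity values),
  normalized to [0, 1].

The parsers read the ASCII formats the profile tools emit (PSI-BLAST
``-out_ascii_pssm`` and HHsuite ``.hhm``); the writers produce the same
layouts so fixtures round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import STANDARD_AA, LabeledChain

__all__ = [
    "ONE_HOT_ALPHABET",
    "N_FEATURES",
    "DEFAULT_HALF_WIDTH",
    "PSSMProfile",
    "HHMProfile",
    "FeatureWindow",
    "ProfileParseError",
    "parse_pssm",
    "write_pssm",
    "parse_hhm",
    "write_hhm",
    "terminal_padding",
    "chain_feature_matrix",
    "assemble_window",
    "featurize_chain",
]

#: One-hot alphabet: 20 standard amino acids alphabetically, then 'X'
#: (unknown residue inside the chain), then '?' (outside the chain).
ONE_HOT_ALPHABET = STANDARD_AA + "X?"

#: Feature block layout per position: one-hot, PSSM round 1, PSSM round 2, HHM.
_N_ONEHOT = 22
_N_PSSM = 20
_N_HHM = 30
N_FEATURES = _N_ONEHOT + 2 * _N_PSSM + _N_HHM  # 92

DEFAULT_HALF_WIDTH = 14

#: Column order of the ASCII PSSM produced by PSI-BLAST.
PSIBLAST_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Log-odds value used for positions outside the chain.
PSSM_PAD_SCORE = -19.0

#: HHM values are stored as non-negative integers; '*' means +infinity and is
#: replaced by this factor, which is also the normalization divisor.
HHM_NORM = 99999.0

#: Names of the 30 per-residue HMM parameters, in storage order.
HHM_PARAM_NAMES = tuple(STANDARD_AA) + (
    "M->M", "M->I", "M->D", "I->M", "I->I", "D->M", "D->D",
    "Neff", "Neff_I", "Neff_D",
)


class ProfileParseError(ValueError):
    """Raised when a PSSM or HHM file cannot be parsed."""


@dataclass(frozen=True)
class PSSMProfile:
    """Per-residue 20-column log-odds scores from one PSI-BLAST round.

    ``scores`` has shape (L, 20) with columns in alphabetical amino-acid
    order (:data:`STANDARD_AA`), regardless of the column order of the source
    file.  The log-odds ("score") form is kept as printed — integers, possibly
    negative, never the weighted percentages.
    """

    scores: np.ndarray
    sequence: str
    round_index: int = 1

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != _N_PSSM:
            raise ValueError("PSSM scores must have shape (L, 20)")
        if self.scores.shape[0] != len(self.sequence):
            raise ValueError("PSSM length differs from its sequence")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class HHMProfile:
    """Per-residue 30-parameter HMM profile, normalized to [0, 1].

    ``values`` has shape (L, 30): 20 emissions (alphabetical), 7 transitions,
    3 diversity (Neff) values, each divided by 99999.0 after '*' entries were
    replaced with 99999.0.
    """

    values: np.ndarray
    sequence: str

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != _N_HHM:
            raise ValueError("HHM values must have shape (L, 30)")
        if self.values.shape[0] != len(self.sequence):
            raise ValueError("HHM length differs from its sequence")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("normalized HHM values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FeatureWindow:
    """A (2*half_width+1, 92) feature matrix centered on one residue."""

    matrix: np.ndarray
    pdb_id: str
    chain_id: str
    center_index: int

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_FEATURES:
            raise ValueError(f"window must have {N_FEATURES} features per position")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def flatten(self) -> np.ndarray:
        return self.matrix.reshape(-1)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def parse_pssm(text: str, round_index: int = 1) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` layout).

    Only the 20 log-odds columns are kept; the weighted-percentage columns
    and the trailing statistics block are ignored.
    """
    lines = text.splitlines()
    header_cols: list | None = None
    rows: list = []
    seq_letters: list = []
    for lineno, line in enumerate(lines, 1):
        parts = line.split()
        if header_cols is None:
            # The column-header line lists 40 amino-acid letters.
            if len(parts) >= 40 and all(len(p) == 1 and p.isalpha() for p in parts[:40]):
                header_cols = parts[:20]
            continue
        if not parts:
            continue
        if not parts[0].isdigit():
            break  # trailing statistics (K, Lambda, ...)
        if len(parts) < 2 + _N_PSSM:
            raise ProfileParseError(
                f"line {lineno}: truncated PSSM row ({len(parts)} fields)"
            )
        try:
            scores = [float(v) for v in parts[2:2 + _N_PSSM]]
        except ValueError as exc:
            raise ProfileParseError(f"line {lineno}: non-numeric score ({exc})") from None
        seq_letters.append(parts[1])
        rows.append(scores)
    if header_cols is None or not rows:
        raise ProfileParseError("no PSSM matrix found in text")

    raw = np.asarray(rows, dtype=np.float64)
    # reorder file columns into alphabetical amino-acid order
    order = [header_cols.index(a) for a in STANDARD_AA]
    return PSSMProfile(
        scores=raw[:, order], sequence="".join(seq_letters), round_index=round_index
    )


def write_pssm(profile: PSSMProfile) -> str:
    """Serialize a profile in the PSI-BLAST ASCII PSSM layout.

    The weighted-percentage block is written as zeros; information-content
    and weight columns are nominal.  ``parse_pssm`` round-trips the scores.
    """
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
    ]
    letters = "   ".join(PSIBLAST_AA_ORDER)
    out.append(" " * 11 + letters + "   " + letters)
    col_of = {a: i for i, a in enumerate(STANDARD_AA)}
    for i, aa in enumerate(profile.sequence, 1):
        scores = profile.scores[i - 1]
        score_txt = "".join(
            f"{int(round(scores[col_of[a]])):4d}" for a in PSIBLAST_AA_ORDER
        )
        pct_txt = "".join(f"{0:4d}" for _ in PSIBLAST_AA_ORDER)
        out.append(f"{i:5d} {aa} {score_txt} {pct_txt}  0.00 0.00")
    out += ["", "                      K         Lambda",
            "Standard Ungapped    0.1337     0.3176", ""]
    return "\n".join(out)


# ---------------------------------------------------------------------------
# HHsuite HHM
# ---------------------------------------------------------------------------

def parse_hhm(text: str) -> HHMProfile:
    """Parse an HHsuite ``.hhm`` profile.

    The header is skipped up to the ``#`` separator line; then the NULL
    model, the two HMM column-header lines, and the begin-state transition
    line are skipped, and per-residue blocks of 20 emission values plus a
    10-value transition/diversity line are read until ``//``.  ``*`` entries
    (zero probability, +infinity in the -1000*log2 encoding) become 99999.0
    before every value is divided by 99999.0.
    """
    lines = text.splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.strip() == "#")
    except StopIteration:
        raise ProfileParseError("no '#' separator found in HHM text") from None

    body = [l for l in lines[start + 1:] if l.strip()]
    # NULL line, 'HMM' emission header, transition header, begin-state line
    if len(body) < 4 or not body[0].startswith("NULL"):
        raise ProfileParseError("missing NULL model line after '#'")
    if not body[1].startswith("HMM"):
        raise ProfileParseError("missing HMM column-header line")
    idx = 4

    def decode(tok: str) -> float:
        if tok == "*":
            return HHM_NORM
        try:
            return float(tok)
        except ValueError:
            raise ProfileParseError(f"bad HHM value {tok!r}") from None

    seq_letters: list = []
    rows: list = []
    while idx < len(body):
        line = body[idx]
        if line.strip() == "//":
            break
        parts = line.split()
        # emission line: AA, position, 20 values, alignment column
        if len(parts) < 2 + 20:
            raise ProfileParseError(
                f"residue block has {len(parts)} fields, expected >= 22"
            )
        aa = parts[0]
        emissions = [decode(t) for t in parts[2:22]]
        if idx + 1 >= len(body):
            raise ProfileParseError("truncated HHM: missing transition line")
        trans_parts = body[idx + 1].split()
        if len(trans_parts) != 10:
            raise ProfileParseError(
                f"transition line has {len(trans_parts)} fields, expected 10"
            )
        transitions = [decode(t) for t in trans_parts]
        seq_letters.append(aa)
        rows.append(emissions + transitions)
        idx += 2

    if not rows:
        raise ProfileParseError("no residue blocks found in HHM text")
    values = np.asarray(rows, dtype=np.float64) / HHM_NORM
    return HHMProfile(values=values, sequence="".join(seq_letters))


def write_hhm(profile: HHMProfile, name: str = "query") -> str:
    """Serialize a profile in the HHsuite ``.hhm`` layout.

    Values equal to 1.0 after normalization are written back as ``*``;
    everything else is written as the original integer (value * 99999).
    """
    def encode(v: float) -> str:
        if v >= 1.0:
            return "*"
        return str(int(round(v * HHM_NORM)))

    out = [
        "HHsearch 1.5",
        f"NAME  {name}",
        f"LENG  {len(profile)} match states",
        "FILT  0",
        "NEFF  1.0",
        "#",
        "NULL   " + " ".join(["3706"] * 20),
        "HMM    " + "\t".join(STANDARD_AA),
        "       " + "\t".join(HHM_PARAM_NAMES[20:]),
        "       0\t*\t*\t0\t*\t0\t*\t*\t*\t*",
    ]
    for i, aa in enumerate(profile.sequence, 1):
        row = profile.values[i - 1]
        out.append(
            f"{aa} {i}    " + "\t".join(encode(v) for v in row[:20]) + f"\t{i}"
        )
        out.append("       " + "\t".join(encode(v) for v in row[20:]))
    out.append("//")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Window assembly
# ---------------------------------------------------------------------------

def terminal_padding() -> np.ndarray:
    """The 92-feature column for a position outside the chain.

    One-hot marks ``?``; both PSSM blocks carry the raw log-odds padding
    value of -19; the first 27 HHM parameters are 99999/99999 = 1.0 and the
    three diversity values (Neff, Neff_I, Neff_D) are 0.0.
    """
    col = np.zeros(N_FEATURES, dtype=np.float64)
    col[ONE_HOT_ALPHABET.index("?")] = 1.0
    col[_N_ONEHOT:_N_ONEHOT + 2 * _N_PSSM] = PSSM_PAD_SCORE
    hhm0 = _N_ONEHOT + 2 * _N_PSSM
    col[hhm0:hhm0 + 27] = 1.0
    col[hhm0 + 27:hhm0 + 30] = 0.0
    return col


def _check_profiles(chain: LabeledChain, *profiles) -> None:
    for p in profiles:
        if len(p) != len(chain):
            raise ValueError(
                f"{chain.key}: profile length {len(p)} != chain length {len(chain)}"
            )


def chain_feature_matrix(
    chain: LabeledChain,
    pssm1: PSSMProfile,
    pssm2: PSSMProfile | None,
    hhm: HHMProfile,
) -> np.ndarray:
    """Per-position (L, 92) feature matrix for a whole chain.

    If no round-2 PSSM is available (profile search converged after one
    round), the round-1 scores are duplicated so the feature width stays 92.
    """
    if pssm2 is None:
        pssm2 = pssm1
    _check_profiles(chain, pssm1, pssm2, hhm)
    L = len(chain)
    mat = np.zeros((L, N_FEATURES), dtype=np.float64)
    for i, aa in enumerate(chain.sequence):
        j = ONE_HOT_ALPHABET.index(aa) if aa in ONE_HOT_ALPHABET[:-1] else ONE_HOT_ALPHABET.index("X")
        mat[i, j] = 1.0
    mat[:, _N_ONEHOT:_N_ONEHOT + _N_PSSM] = pssm1.scores
    mat[:, _N_ONEHOT + _N_PSSM:_N_ONEHOT + 2 * _N_PSSM] = pssm2.scores
    mat[:, _N_ONEHOT + 2 * _N_PSSM:] = hhm.values
    return mat


def _padded_windows(feature_matrix: np.ndarray, half_width: int) -> np.ndarray:
    """(L, 2w+1, 92) view of all windows over a padded feature matrix."""
    pad = np.tile(terminal_padding(), (half_width, 1))
    padded = np.vstack([pad, feature_matrix, pad])
    win = np.lib.stride_tricks.sliding_window_view(
        padded, 2 * half_width + 1, axis=0
    )
    # sliding_window_view yields (L, 92, 2w+1); put positions first
    return np.ascontiguousarray(np.transpose(win, (0, 2, 1)))


def assemble_window(
    chain: LabeledChain,
    pssm1: PSSMProfile,
    pssm2: PSSMProfile | None,
    hhm: HHMProfile,
    center: int,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> FeatureWindow:
    """The feature window centered on ``center`` (0-based chain index)."""
    if not 0 <= center < len(chain):
        raise IndexError(f"center {center} outside chain of length {len(chain)}")
    mat = chain_feature_matrix(chain, pssm1, pssm2, hhm)
    windows = _padded_windows(mat, half_width)
    return FeatureWindow(
        matrix=windows[center],
        pdb_id=chain.pdb_id,
        chain_id=chain.chain_id,
        center_index=center,
    )


def featurize_chain(
    chain: LabeledChain,
    pssm1: PSSMProfile,
    pssm2: PSSMProfile | None,
    hhm: HHMProfile,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> list:
    """All (FeatureWindow, label8) samples for a chain.

    One sample per residue with an assigned label; disordered residues
    ('X') yield no samples but still contribute context inside windows.
    """
    mat = chain_feature_matrix(chain, pssm1, pssm2, hhm)
    windows = _padded_windows(mat, half_width)
    samples = []
    for i, lab in enumerate(chain.labels8):
        if lab == "X":
            continue
        samples.append(
            (
                FeatureWindow(
                    matrix=windows[i],
                    pdb_id=chain.pdb_id,
                    chain_id=chain.chain_id,
                    center_index=i,
                ),
                lab,
            )
        )
    return samples
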