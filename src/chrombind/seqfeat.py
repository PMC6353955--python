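"""Protein-sequence features used to model the mitotic bound fraction.

Each transcription factor is summarized by physico-chemical sequence
descriptors: amino-acid category fractions (positively charged, aromatic,
polar, hydrophobic aliphatic, tiny, bulky, small), the summed Kyte-
Doolittle hydropathy (GRAVY sum), residues in charge runs, intrinsic-
disorder content (from an externally supplied per-residue mask), the net
charge of the DNA-binding domain(s), the dispersion of positive charges
along the chain, single-residue composition fractions and one-hot DBD
family membership.  Count-valued descriptors are min-max normalized across
the cohort so every column lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Default residue category table.  The categories follow the common
#: physico-chemical grouping used for TF sequence analysis; the table is a
#: plain mapping and can be replaced wholesale by the caller.
DEFAULT_CATEGORY_MAP: dict[str, frozenset] = {
    "positively_charged": frozenset("RKH"),
    "aromatic": frozenset("FWYH"),
    "polar": frozenset("NQSTCHDERK"),
    "hydrophobic_aliphatic": frozenset("AVLIM"),
    "tiny": frozenset("AGSC"),
    "small": frozenset("AGSCNDTPV"),
    "bulky": frozenset("FWYRKILMH"),
}

#: Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

BASIC = frozenset("RK")
ACIDIC = frozenset("DE")


@dataclass
class ProteinRecord:
    """One TF: sequence, DBD annotation, disorder mask and (optionally) MBF."""

    tf_id: str
    sequence: str
    dbd_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    disorder_mask: np.ndarray | None = None
    mbf: float | None = None

    def __post_init__(self) -> None:
        if self.disorder_mask is not None:
            self.disorder_mask = np.asarray(self.disorder_mask, dtype=bool)
            if self.disorder_mask.size != len(self.sequence):
                raise ValueError(f"{self.tf_id}: disorder mask length != sequence length")
        for start, end, _fam in self.dbd_intervals:
            if not 0 <= start < end <= len(self.sequence):
                raise ValueError(f"{self.tf_id}: DBD interval outside sequence")


@dataclass
class FeatureMatrix:
    """Cohort feature table with its per-column normalization record."""

    values: pd.DataFrame  # index tf_id, columns = feature names
    normalization: dict[str, tuple[float, float]]  # column -> (min, max)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"unknown residue letter(s): {''.join(sorted(bad))}")
    return sequence


def composition_features(sequence: str, category_map: dict | None = None) -> dict[str, float]:
    """Fraction of residues in each physico-chemical category."""
    sequence = _check_sequence(sequence)
    category_map = category_map or DEFAULT_CATEGORY_MAP
    n = len(sequence)
    return {
        f"frac_{name}": sum(1 for r in sequence if r in members) / n
        for name, members in category_map.items()
    }


def aa_composition(sequence: str) -> dict[str, float]:
    """Single-residue composition fractions (20 features)."""
    sequence = _check_sequence(sequence)
    n = len(sequence)
    return {f"frac_{a}": sequence.count(a) / n for a in AA_ALPHABET}


def gravy_sum(sequence: str) -> float:
    """Summed Kyte-Doolittle hydropathy over all residues."""
    sequence = _check_sequence(sequence)
    return float(sum(KYTE_DOOLITTLE[r] for r in sequence))


def _runs(classes: list[int]) -> list[tuple[int, int]]:
    """(class, run_length) encoding of a class sequence."""
    out = []
    for c in classes:
        if out and out[-1][0] == c:
            out[-1] = (c, out[-1][1] + 1)
        else:
            out.append((c, 1))
    return out


def charge_run_counts(sequence: str, mode: str = "residues") -> tuple[int, int, int]:
    """Residues in charge runs: (positive, neutral, negative).

    Residues are classed positive (R, K), negative (D, E) or neutral; a run
    is a maximal stretch of >= 2 same-class residues.  ``mode`` selects the
    statistic: ``"residues"`` (total residues in runs, the default
    convention), ``"runs"`` (number of runs) or ``"longest"`` (longest run).
    """
    sequence = _check_sequence(sequence)
    cls = [0 if r in BASIC else (2 if r in ACIDIC else 1) for r in sequence]
    counts = [0, 0, 0]
    for c, length in _runs(cls):
        if length < 2:
            continue
        if mode == "residues":
            counts[c] += length
        elif mode == "runs":
            counts[c] += 1
        elif mode == "longest":
            counts[c] = max(counts[c], length)
        else:
            raise ValueError("mode must be 'residues', 'runs' or 'longest'")
    return counts[0], counts[1], counts[2]


def _merge_intervals(intervals):
    merged = []
    for start, end in sorted((s, e) for s, e, *_ in intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(end, merged[-1][1]))
        else:
            merged.append((start, end))
    return merged


def dbd_net_charge(sequence: str, dbd_intervals, per_dbd_mean: bool = False) -> float:
    """Basic minus acidic residues over the union of DBD intervals.

    With ``per_dbd_mean`` the net charge is averaged across the individual
    (unmerged) intervals instead.
    """
    sequence = _check_sequence(sequence)
    if not dbd_intervals:
        raise ValueError("at least one DBD interval required")
    if per_dbd_mean:
        charges = []
        for start, end, *_ in dbd_intervals:
            seg = sequence[start:end]
            charges.append(sum(r in BASIC for r in seg) - sum(r in ACIDIC for r in seg))
        return float(np.mean(charges))
    net = 0
    for start, end in _merge_intervals(dbd_intervals):
        seg = sequence[start:end]
        net += sum(r in BASIC for r in seg) - sum(r in ACIDIC for r in seg)
    return float(net)


def positive_charge_dispersion(sequence: str, window: int = 5) -> float:
    """Variance-over-mean of R/K counts in a sliding window.

    All length-``window`` windows (step 1) are scored by their number of
    arginine and lysine residues; the statistic is the population variance
    of those sums divided by their mean (0 when the mean is 0).
    """
    sequence = _check_sequence(sequence)
    if len(sequence) < window:
        raise ValueError(f"sequence shorter than window ({window})")
    is_pos = np.fromiter((r in BASIC for r in sequence), dtype=float)
    kernel = np.ones(window)
    sums = np.convolve(is_pos, kernel, mode="valid")
    mean = sums.mean()
    if mean == 0:
        return 0.0
    return float(sums.var() / mean)  # population variance


def disorder_features(disorder_mask) -> tuple[int, float]:
    """(residues in disordered domains, fraction of the sequence).

    A disordered domain is a maximal run of *more than 5* consecutive
    disordered residues; shorter runs do not count.
    """
    mask = np.asarray(disorder_mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty disorder mask")
    total = 0
    for c, length in _runs(list(mask.astype(int))):
        if c == 1 and length > 5:
            total += length
    return total, total / mask.size


def feature_vector(
    record: ProteinRecord,
    category_map: dict | None = None,
    window: int = 5,
    include_aa_composition: bool = True,
) -> dict[str, float | None]:
    """All sequence features of one record (``None`` marks a missing value)."""
    feats: dict[str, float | None] = {}
    feats.update(composition_features(record.sequence, category_map))
    if include_aa_composition:
        feats.update(aa_composition(record.sequence))
    feats["gravy_sum"] = gravy_sum(record.sequence)
    pos, neu, neg = charge_run_counts(record.sequence)
    feats["positive_run_residues"] = pos
    feats["neutral_run_residues"] = neu
    feats["negative_run_residues"] = neg
    feats["positive_charge_dispersion"] = (
        positive_charge_dispersion(record.sequence, window)
        if len(record.sequence) >= window
        else None
    )
    if record.disorder_mask is not None:
        dsum, dfrac = disorder_features(record.disorder_mask)
        feats["disorder_sum"] = dsum
        feats["disorder_fraction"] = dfrac
    else:
        feats["disorder_sum"] = None
        feats["disorder_fraction"] = None
    feats["dbd_net_charge"] = (
        dbd_net_charge(record.sequence, record.dbd_intervals)
        if record.dbd_intervals
        else None
    )
    return feats

#: columns that are unbounded counts/sums and get min-max normalized
NORMALIZED_COLUMNS = (
    "gravy_sum",
    "positive_run_residues",
    "neutral_run_residues",
    "negative_run_residues",
    "positive_charge_dispersion",
    "disorder_sum",
    "dbd_net_charge",
)


def build_feature_matrix(
    records: list[ProteinRecord],
    category_map: dict | None = None,
    family_min_count: int = 10,
    window: int = 5,
    include_aa_composition: bool = True,
) -> FeatureMatrix:
    """Assemble the cohort TF x feature table.

    DBD-family one-hot columns are emitted only for families present in
    more than ``family_min_count`` records (a multi-DBD TF contributes to
    each of its families).  Records with any missing feature are dropped.
    Count-valued columns are min-max normalized across the retained cohort.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    family_counts: dict[str, int] = {}
    for rec in records:
        for fam in {f for _, _, f in rec.dbd_intervals}:
            family_counts[fam] = family_counts.get(fam, 0) + 1
    families = sorted(f for f, c in family_counts.items() if c > family_min_count)

    rows, index = [], []
    for rec in records:
        feats = feature_vector(
            rec, category_map=category_map, window=window,
            include_aa_composition=include_aa_composition,
        )
        if any(v is None for v in feats.values()):
            continue
        rec_fams = {f for _, _, f in rec.dbd_intervals}
        for fam in families:
            feats[f"dbd_family_{fam}"] = float(fam in rec_fams)
        rows.append(feats)
        index.append(rec.tf_id)
    if not rows:
        raise ValueError("all records dropped (missing values)")
    df = pd.DataFrame(rows, index=index, dtype=float)

    normalization: dict[str, tuple[float, float]] = {}
    for col in NORMALIZED_COLUMNS:
        lo, hi = float(df[col].min()), float(df[col].max())
        normalization[col] = (lo, hi)
        df[col] = 0.0 if hi == lo else (df[col] - lo) / (hi - lo)
    return FeatureMatrix(values=df, normalization=normalization)
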