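"""Pairwise site-pattern counting and evolutionary distances.

Distances are expressed in expected substitutions per site.  Three models
are supported:

``p``
    Raw proportion of differing compared sites.
``jc``
    Jukes-Cantor correction, ``-3/4 ln(1 - 4p/3)``.
``k2p``
    Kimura two-parameter correction, distinguishing transitions
    (purine<->purine, pyrimidine<->pyrimidine) from transversions:

        d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

    with P and Q the transition and transversion proportions among
    compared sites.

A site is *compared* for a pair only when both characters are canonical
bases (A, C, G, T).  Under pairwise deletion each pair skips its own
non-canonical sites; under complete deletion the excluded column set is
fixed once for the whole alignment.  When the logarithm argument is
non-positive the distance is *saturated* and reported as undefined (NaN)
rather than clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LocusAlignment, SampleSheet

__all__ = [
    "SiteCounts",
    "DistanceMatrix",
    "IntraSpecificSummary",
    "DivergenceSummary",
    "encode_sequence",
    "count_site_patterns",
    "complete_deletion_columns",
    "p_distance",
    "jc_distance",
    "k2p_distance",
    "distance_from_counts",
    "pairwise_distance_matrix",
    "intra_specific_summary",
    "inter_specific_matrix",
]

MODELS = ("p", "jc", "k2p")
DELETION_POLICIES = ("pairwise", "complete")

# A=0, C=1, G=2, T=3; anything else (gap, N, ?, IUPAC ambiguity) = 4.
# Purines are even, pyrimidines odd, and the transition partner is
# ``base ^ 2`` — properties the counting kernel relies on.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
MISSING_CODE = 4


def encode_sequence(seq: str | np.ndarray) -> np.ndarray:
    """Encode a sequence string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    if isinstance(seq, np.ndarray):
        return seq
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SiteCounts:
    """Compared-site and mismatch-type counts for one sequence pair."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if min(self.n_compared, self.n_transitions, self.n_transversions) < 0:
            raise ValueError("site counts must be non-negative")
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("mismatches exceed compared sites")

    @property
    def empty_overlap(self) -> bool:
        return self.n_compared == 0

    @property
    def P(self) -> float:
        """Transition proportion among compared sites."""
        return self.n_transitions / self.n_compared

    @property
    def Q(self) -> float:
        """Transversion proportion among compared sites."""
        return self.n_transversions / self.n_compared


def count_site_patterns(
    a: str | np.ndarray,
    b: str | np.ndarray,
    deletion: str = "pairwise",
    excluded_columns: np.ndarray | None = None,
) -> SiteCounts:
    """Count compared sites, transitions and transversions for one pair.

    Under ``deletion="complete"`` the caller supplies ``excluded_columns``
    (a boolean mask, typically from :func:`complete_deletion_columns`)
    fixed for the whole dataset.  An all-missing overlap yields
    ``SiteCounts(0, 0, 0)`` — flagged, not an error.
    """
    if deletion not in DELETION_POLICIES:
        raise ValueError(f"unknown deletion policy {deletion!r}")
    ca, cb = encode_sequence(a), encode_sequence(b)
    if ca.shape != cb.shape:
        raise ValueError(f"length mismatch: {ca.size} vs {cb.size}")
    ok = (ca != MISSING_CODE) & (cb != MISSING_CODE)
    if deletion == "complete":
        if excluded_columns is None:
            raise ValueError("complete deletion requires excluded_columns")
        ok &= ~excluded_columns
    diff = ok & (ca != cb)
    # transitions stay within purines {0,2} or pyrimidines {1,3}: parity equal
    ts = diff & ((ca & 1) == (cb & 1))
    n_diff = int(diff.sum())
    n_ts = int(ts.sum())
    return SiteCounts(int(ok.sum()), n_ts, n_diff - n_ts)


def complete_deletion_columns(seqs: Iterable[str | np.ndarray]) -> np.ndarray:
    """Boolean mask of columns containing any non-canonical character."""
    mask: np.ndarray | None = None
    for s in seqs:
        c = encode_sequence(s)
        bad = c == MISSING_CODE
        mask = bad if mask is None else (mask | bad)
    if mask is None:
        raise ValueError("no sequences given")
    return mask


def p_distance(c: SiteCounts) -> float:
    """Proportion of differing compared sites; NaN on empty overlap."""
    if c.empty_overlap:
        return math.nan
    return (c.n_transitions + c.n_transversions) / c.n_compared


def jc_distance(c: SiteCounts) -> float:
    """Jukes-Cantor distance; NaN when saturated (p >= 3/4) or empty."""
    if c.empty_overlap:
        return math.nan
    # exact integer arithmetic so the saturation boundary (p = 3/4) is sharp
    n, d = c.n_compared, c.n_transitions + c.n_transversions
    num = 3 * n - 4 * d
    if num <= 0:
        return math.nan
    return -0.75 * math.log(num / (3 * n)) + 0.0  # +0.0 normalizes -0.0


def k2p_distance(c: SiteCounts) -> float:
    """Kimura two-parameter distance; NaN when saturated or empty overlap.

    Saturation means ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``; such pairs
    are diverged beyond what the correction can express and are flagged
    undefined instead of being clamped to a finite value.
    """
    if c.empty_overlap:
        return math.nan
    # numerators kept in exact integers so the saturation boundary
    # (1 - 2P - Q = 0 or 1 - 2Q = 0) is detected sharply
    n = c.n_compared
    num1 = n - 2 * c.n_transitions - c.n_transversions
    num2 = n - 2 * c.n_transversions
    if num1 <= 0 or num2 <= 0:
        return math.nan
    return -0.5 * math.log(num1 / n) - 0.25 * math.log(num2 / n) + 0.0


_DISTANCE_FNS = {"p": p_distance, "jc": jc_distance, "k2p": k2p_distance}


def distance_from_counts(c: SiteCounts, model: str = "k2p") -> float:
    try:
        return _DISTANCE_FNS[model](c)
    except KeyError:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}") from None


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with undefined-pair flags.

    ``values`` holds NaN for undefined (saturated or empty-overlap) pairs;
    the diagonal is zero.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    model: str
    deletion: str

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def undefined_mask(self) -> np.ndarray:
        """Boolean matrix: True where a pair's distance is undefined."""
        m = np.isnan(self.values)
        np.fill_diagonal(m, False)
        return m

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def pairs(self):
        """Yield (label_i, label_j, distance) over unordered pairs (i<j)."""
        for i in range(self.n):
            for j in range(i + 1, self.n):
                yield self.labels[i], self.labels[j], float(self.values[i, j])

    def defined_offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        vals = self.values[iu]
        return vals[~np.isnan(vals)]

    def mean_and_range(self) -> tuple[float, tuple[float, float]]:
        """Mean and (min, max) over defined unordered pairs."""
        vals = self.defined_offdiagonal()
        if vals.size == 0:
            return math.nan, (math.nan, math.nan)
        return float(vals.mean()), (float(vals.min()), float(vals.max()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path, decimals: int = 4) -> None:
        """Square TSV; undefined entries written as NA."""
        df = self.to_dataframe().round(decimals)
        df.to_csv(path, sep="\t", na_rep="NA")

    def write_phylip(self, path: str | Path, decimals: int = 4) -> None:
        """PHYLIP-style square matrix; undefined entries written as NA."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for lab, row in zip(self.labels, self.values):
                cells = " ".join(
                    "NA" if math.isnan(v) else f"{v:.{decimals}f}" for v in row
                )
                fh.write(f"{lab:<12s}{cells}\n")


def pairwise_distance_matrix(
    sequences: LocusAlignment | Mapping[str, str] | Sequence[tuple[str, str]],
    model: str = "k2p",
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """All unordered pairwise distances over a set of labelled sequences.

    Accepts a :class:`LocusAlignment` (labelled by accession id), a
    mapping label → sequence, or (label, sequence) pairs.  Saturated and
    empty-overlap pairs come back as NaN, flagged via ``undefined_mask``.
    """
    if isinstance(sequences, LocusAlignment):
        items = [(r.accession_id, r.sequence) for r in sequences.records]
    elif isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = list(sequences)
    if len(items) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    labels = tuple(lab for lab, _ in items)
    codes = [encode_sequence(s) for _, s in items]
    excluded = complete_deletion_columns(codes) if deletion == "complete" else None
    n = len(items)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            c = count_site_patterns(codes[i], codes[j], deletion, excluded)
            d = distance_from_counts(c, model)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values, model=model, deletion=deletion)


@dataclass(frozen=True)
class IntraSpecificSummary:
    """Within-species pairwise distances for one locus (accession level).

    Species with a single accession contribute nothing; ``intra_max`` is
    the global maximum over all included species, the quantity used as
    the discrimination threshold.  Undefined (NaN) within-species pairs
    are dropped from the statistics.
    """

    locus_name: str
    per_species: Mapping[str, tuple[float, ...]]
    warnings: tuple[str, ...] = ()

    @property
    def n_species(self) -> int:
        return len(self.per_species)

    def all_distances(self) -> np.ndarray:
        flat = [d for ds in self.per_species.values() for d in ds if not math.isnan(d)]
        return np.asarray(flat, dtype=float)

    @property
    def intra_max(self) -> float:
        vals = self.all_distances()
        return float(vals.max()) if vals.size else 0.0

    @property
    def intra_range(self) -> tuple[float, float]:
        vals = self.all_distances()
        if vals.size == 0:
            return (0.0, 0.0)
        return (float(vals.min()), float(vals.max()))


@dataclass(frozen=True)
class DivergenceSummary:
    """Per-scope intra/inter divergence summary (one table row)."""

    scope_id: str
    n_species_intra: int
    intra_min: float
    intra_max: float
    n_species_inter: int
    inter_mean: float
    inter_min: float
    inter_max: float


def intra_specific_summary(
    aln: LocusAlignment,
    sheet: SampleSheet | None = None,
    model: str = "k2p",
    deletion: str = "pairwise",
) -> IntraSpecificSummary:
    """All within-species pairwise distances, singletons excluded.

    Species labels are taken from the alignment records (annotated at
    dataset build); ``sheet`` is accepted for symmetry but only used to
    resolve labels when records are unannotated.
    """
    by_species: dict[str, list] = {}
    for rec in aln.records:
        label = rec.species_label
        if not label and sheet is not None:
            label = sheet.species_of(rec.accession_id)
        if not label:
            raise ValueError(
                f"record {rec.accession_id!r} has no species label; "
                "build the dataset from a sample sheet first"
            )
        by_species.setdefault(label, []).append(rec)

    excluded = None
    if deletion == "complete":
        excluded = complete_deletion_columns(r.sequence for r in aln.records)

    warnings: list[str] = []
    per_species: dict[str, tuple[float, ...]] = {}
    for label, recs in by_species.items():
        if len(recs) < 2:
            continue
        codes = [encode_sequence(r.sequence) for r in recs]
        dists = []
        for i in range(len(codes)):
            for j in range(i + 1, len(codes)):
                c = count_site_patterns(codes[i], codes[j], deletion, excluded)
                dists.append(distance_from_counts(c, model))
        per_species[label] = tuple(dists)
    if not per_species:
        warnings.append(
            f"locus {aln.locus_name!r}: no species with >= 2 accessions; "
            "intra-specific maximum defined as 0"
        )
    return IntraSpecificSummary(
        locus_name=aln.locus_name,
        per_species=per_species,
        warnings=tuple(warnings),
    )


def inter_specific_matrix(
    representatives: Mapping[str, str],
    model: str = "k2p",
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """Distance matrix over one representative sequence per species."""
    if len(representatives) < 2:
        raise ValueError("inter-specific distances need at least 2 species")
    return pairwise_distance_matrix(representatives, model=model, deletion=deletion)
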