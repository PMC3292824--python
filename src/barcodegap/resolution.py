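"""Threshold-based species discrimination and percent species resolution.

The barcode-gap rule used here: two species are distinct at a scope (a
locus or a concatenation of loci) when their inter-specific distance is
strictly greater than the maximum intra-specific distance recorded at
that scope (the threshold tau).  The headline statistic is

    percent resolution = (A - B) * 100 / A

where A is the number of species analyzed and B the number of distinct
species appearing in at least one unresolved pair.  With tau = 0 (no
intra-specific variation, typical of plastid loci in congeneric plants),
"unresolved" reduces to "zero distance estimate".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .consensus import SpeciesProfile, build_species_profiles, representatives_for_locus
from .distances import (
    DistanceMatrix,
    DivergenceSummary,
    IntraSpecificSummary,
    inter_specific_matrix,
    intra_specific_summary,
)
from .io import AlignedRecord, BarcodeDataset, LocusAlignment, validate_dataset

__all__ = [
    "LocusThreshold",
    "CombinationSpec",
    "ResolutionResult",
    "AnalysisBundle",
    "round_half_up",
    "locus_threshold",
    "discriminate_pair",
    "unresolved_pairs_from_matrix",
    "resolution_percent",
    "combine_loci",
    "analyze_dataset",
    "all_subsets",
]


def round_half_up(value: float | int, places: int = 2) -> float:
    """Decimal round-half-up (29/36 -> 80.56, not banker's 80.55...)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LocusThreshold:
    """Discrimination threshold for a scope: the intra-specific maximum."""

    scope_id: str
    tau: float
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("threshold must be non-negative")


@dataclass(frozen=True)
class CombinationSpec:
    """An ordered multi-locus concatenation, e.g. matK+rpoB+rpoC1."""

    member_loci: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_loci:
            raise ValueError("combination needs at least one locus")
        if len(set(self.member_loci)) != len(self.member_loci):
            raise ValueError(f"duplicate loci in combination {self.member_loci}")

    @property
    def id(self) -> str:
        return "+".join(self.member_loci)

    @classmethod
    def parse(cls, text: str) -> "CombinationSpec":
        return cls(tuple(p.strip() for p in text.split("+") if p.strip()))


@dataclass(frozen=True)
class ResolutionResult:
    """Resolution outcome for one scope.

    A = species analyzed, B = species in the unresolved-pair union,
    C = A - B discriminated, percent = (A - B) * 100 / A half-up to two
    decimals.
    """

    scope_id: str
    n_species: int
    unresolved_pairs: tuple[tuple[str, str], ...]
    tau: float = 0.0
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("scope must analyze at least one species")

    @property
    def A(self) -> int:
        return self.n_species

    @property
    def unresolved_species(self) -> frozenset[str]:
        return frozenset(s for pair in self.unresolved_pairs for s in pair)

    @property
    def B(self) -> int:
        return len(self.unresolved_species)

    @property
    def C(self) -> int:
        return self.A - self.B

    @property
    def n_unresolved_pairs(self) -> int:
        return len(self.unresolved_pairs)

    @property
    def percent(self) -> float:
        return round_half_up((self.A - self.B) * 100.0 / self.A, 2)


def locus_threshold(intra: IntraSpecificSummary, scope_id: str | None = None) -> LocusThreshold:
    """tau = maximum intra-specific distance at the scope (0 when none exists)."""
    return LocusThreshold(
        scope_id=scope_id or intra.locus_name,
        tau=intra.intra_max,
        warnings=intra.warnings,
    )


def discriminate_pair(d_inter: float, tau: float) -> bool:
    """True (resolved) iff d_inter > tau, strictly.

    An undefined distance (NaN: saturated beyond the model's range) is
    treated as resolved — saturation implies divergence far above any
    intra-specific threshold.
    """
    if math.isnan(d_inter):
        return True
    return d_inter > tau


def unresolved_pairs_from_matrix(
    matrix: DistanceMatrix, tau: float
) -> tuple[tuple[tuple[str, str], ...], tuple[str, ...]]:
    """Species pairs failing the threshold rule, plus warnings for NaN pairs."""
    unresolved: list[tuple[str, str]] = []
    warnings: list[str] = []
    for a, b, d in matrix.pairs():
        if math.isnan(d):
            warnings.append(
                f"pair ({a}, {b}): distance undefined (saturated or no overlap); "
                "treated as resolved"
            )
        elif not discriminate_pair(d, tau):
            unresolved.append((a, b))
    return tuple(unresolved), tuple(warnings)


def resolution_percent(
    n_species: int,
    unresolved_pairs: Iterable[tuple[str, str]],
    scope_id: str = "scope",
    known_species: Iterable[str] | None = None,
    tau: float = 0.0,
) -> ResolutionResult:
    """Build a :class:`ResolutionResult` from A and the unresolved pairs.

    ``known_species``, when given, is the full species set of the scope;
    any pair member outside it is an error.  B never double-counts a
    species appearing in several pairs.
    """
    pairs = tuple(tuple(p) for p in unresolved_pairs)
    for p in pairs:
        if len(p) != 2 or p[0] == p[1]:
            raise ValueError(f"malformed species pair {p!r}")
    if known_species is not None:
        known = set(known_species)
        if len(known) != n_species:
            raise ValueError("known_species size disagrees with n_species")
        stray = {s for pair in pairs for s in pair} - known
        if stray:
            raise ValueError(f"unresolved pairs reference unknown species {sorted(stray)}")
    result = ResolutionResult(
        scope_id=scope_id, n_species=n_species, unresolved_pairs=pairs, tau=tau
    )
    if result.B > n_species:
        raise ValueError("more unresolved species than species analyzed")
    return result


def _concatenate(parts: Sequence[str]) -> str:
    return "".join(parts)


def combine_loci(
    ds: BarcodeDataset,
    profiles: Mapping[str, SpeciesProfile],
    spec: CombinationSpec,
) -> tuple[dict[str, str], list[AlignedRecord], tuple[str, ...]]:
    """Concatenated representatives and accession data for a combination.

    The species set is the intersection of species carrying every member
    locus.  Representatives are concatenated in spec order; intra-specific
    data are concatenations of accession-level sequences for accessions
    present at all member loci, so the combination's threshold and
    distances come from pooled site counts across the members.

    Returns (species → concatenated representative, concatenated
    accession records, species order).
    """
    for locus in spec.member_loci:
        if locus not in ds.loci:
            raise KeyError(f"combination references unknown locus {locus!r}")
    species = [
        label
        for label, prof in profiles.items()
        if all(l in prof.representatives for l in spec.member_loci)
    ]
    if not species:
        raise ValueError(f"no species carries every locus of {spec.id}")
    reps = {
        label: _concatenate(
            [profiles[label].representatives[l] for l in spec.member_loci]
        )
        for label in species
    }
    # accessions sequenced at every member locus
    per_locus_seqs: list[dict[str, AlignedRecord]] = [
        {r.accession_id: r for r in ds.loci[l].records} for l in spec.member_loci
    ]
    common_acc = set(per_locus_seqs[0])
    for m in per_locus_seqs[1:]:
        common_acc &= set(m)
    records = []
    for acc in sorted(common_acc):
        label = per_locus_seqs[0][acc].species_label
        if label not in reps:
            continue
        seq = _concatenate([m[acc].sequence for m in per_locus_seqs])
        records.append(AlignedRecord(accession_id=acc, sequence=seq, species_label=label))
    return reps, records, tuple(species)


@dataclass
class AnalysisBundle:
    """Machine-readable results for every scope of one analysis run."""

    model: str
    deletion: str
    divergence: dict[str, DivergenceSummary] = field(default_factory=dict)
    resolution: dict[str, ResolutionResult] = field(default_factory=dict)
    validation_warnings: tuple[str, ...] = ()

    def scopes(self) -> tuple[str, ...]:
        return tuple(self.resolution)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "deletion": self.deletion,
            "validation_warnings": list(self.validation_warnings),
            "scopes": {
                sid: {
                    "n_species": r.n_species,
                    "tau": r.tau,
                    "n_unresolved_pairs": r.n_unresolved_pairs,
                    "B": r.B,
                    "C": r.C,
                    "percent": r.percent,
                    "unresolved_pairs": [list(p) for p in r.unresolved_pairs],
                    "warnings": list(r.warnings),
                    "divergence": (
                        vars(self.divergence[sid]) if sid in self.divergence else None
                    ),
                }
                for sid, r in self.resolution.items()
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        # insertion order kept: rendering must be reproducible from the JSON
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _analyze_scope(
    scope_id: str,
    reps: Mapping[str, str],
    intra: IntraSpecificSummary,
    model: str,
    deletion: str,
) -> tuple[DivergenceSummary, ResolutionResult]:
    thr = locus_threshold(intra, scope_id)
    matrix = inter_specific_matrix(reps, model=model, deletion=deletion)
    unresolved, warn = unresolved_pairs_from_matrix(matrix, thr.tau)
    mean, (lo, hi) = matrix.mean_and_range()
    intra_lo, intra_hi = intra.intra_range
    div = DivergenceSummary(
        scope_id=scope_id,
        n_species_intra=intra.n_species,
        intra_min=intra_lo,
        intra_max=intra_hi,
        n_species_inter=len(reps),
        inter_mean=mean,
        inter_min=lo,
        inter_max=hi,
    )
    res = ResolutionResult(
        scope_id=scope_id,
        n_species=len(reps),
        unresolved_pairs=unresolved,
        tau=thr.tau,
        warnings=thr.warnings + warn,
    )
    return div, res


def analyze_dataset(
    ds: BarcodeDataset,
    combinations: Sequence[CombinationSpec] = (),
    model: str = "k2p",
    deletion: str = "pairwise",
) -> AnalysisBundle:
    """Full analysis: per-locus and per-combination divergence + resolution.

    Deterministic: rerunning on identical input yields an identical
    bundle.
    """
    report = validate_dataset(ds)
    if not report.ok:
        raise ValueError("dataset validation failed: " + "; ".join(report.errors))
    profiles = build_species_profiles(ds)
    bundle = AnalysisBundle(
        model=model, deletion=deletion, validation_warnings=tuple(report.warnings)
    )
    for locus_name, aln in ds.loci.items():
        intra = intra_specific_summary(aln, model=model, deletion=deletion)
        reps = representatives_for_locus(profiles, locus_name)
        if len(reps) < 2:
            bundle.resolution[locus_name] = ResolutionResult(
                scope_id=locus_name,
                n_species=len(reps),
                unresolved_pairs=(),
                tau=intra.intra_max,
                warnings=("fewer than 2 species; nothing to discriminate",),
            )
            continue
        div, res = _analyze_scope(locus_name, reps, intra, model, deletion)
        bundle.divergence[locus_name] = div
        bundle.resolution[locus_name] = res
    for spec in combinations:
        reps, records, _species = combine_loci(ds, profiles, spec)
        combo_aln = LocusAlignment(locus_name=spec.id, records=tuple(records))
        intra = intra_specific_summary(combo_aln, model=model, deletion=deletion)
        div, res = _analyze_scope(spec.id, reps, intra, model, deletion)
        bundle.divergence[spec.id] = div
        bundle.resolution[spec.id] = res
    return bundle


def all_subsets(loci: Sequence[str], max_size: int) -> list[CombinationSpec]:
    """Every non-empty combination of the given loci up to ``max_size``."""
    from itertools import combinations as icombs

    out = []
    for k in range(1, min(max_size, len(loci)) + 1):
        for combo in icombs(loci, k):
            out.append(CombinationSpec(tuple(combo)))
    return out
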