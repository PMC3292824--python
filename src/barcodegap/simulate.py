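"""Ground-truthed simulator of congeneric multi-locus barcode datasets.

The generator emulates the statistical structure a congeneric barcoding
study presents to the analysis: many species of one genus sampled at a
handful of plastid loci plus one nuclear locus, with near-zero
intra-specific divergence at the plastid loci, appreciably larger
intra-specific divergence at the nuclear locus, and optionally one or
more species pairs sharing an identical plastid haplotype (plastid
capture), which defeats plastid-only barcodes by construction.

Species sit on a star topology: every species' founding haplotype is
evolved independently from a common ancestral sequence along a branch of
half the configured inter-specific divergence, so the expected pairwise
divergence between any two founders is ``inter_divergence`` and expected
values stay closed-form.  Accessions are evolved from their species
founder along branches of half the configured intra-specific divergence
(so conspecific accession pairs diverge by ``intra_divergence`` in
expectation).  Evolution is substitution-only under the Kimura
two-parameter process — per-site changes are drawn from the exact K2P
transition-probability matrix for the branch length — so simulated
sequences are born aligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .distances import encode_sequence
from .io import (
    AlignedRecord,
    BarcodeDataset,
    LocusAlignment,
    SampleSheet,
    build_dataset,
)

__all__ = [
    "LocusModel",
    "SimulationConfig",
    "GenusTruth",
    "k2p_transition_probs",
    "evolve_sequence",
    "simulate_genus",
    "dendrobium_like_config",
]

_DECODE = np.array(list("ACGT"))


@dataclass(frozen=True)
class LocusModel:
    """One simulated locus: name, aligned length, and genome of origin."""

    name: str
    length: int
    genome: str  # "nuclear" or "plastid"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("locus length must be positive")
        if self.genome not in ("nuclear", "plastid"):
            raise ValueError(f"genome must be nuclear/plastid, got {self.genome!r}")


@dataclass
class SimulationConfig:
    """Parameters of one simulated genus.

    ``inter_divergence`` and ``intra_divergence`` are expected pairwise
    substitutions/site between two species' founders and between two
    conspecific accessions respectively, per locus (a scalar applies to
    all loci).  ``plastid_capture_pairs`` lists species pairs whose
    plastid founding haplotypes are copied verbatim from the first to
    the second member.  ``accessions_per_species`` may be a single count
    or a per-species map (value 1 makes a singleton).  ``seed`` is
    mandatory; all randomness flows from one numpy Generator.
    """

    n_species: int
    accessions_per_species: int | Mapping[str, int]
    loci: Sequence[LocusModel]
    kappa: float
    inter_divergence: float | Mapping[str, float]
    intra_divergence: float | Mapping[str, float]
    seed: int
    plastid_capture_pairs: Sequence[tuple[str, str]] = ()
    missing_loci: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def species_labels(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"species_{i + 1:0{width}d}" for i in range(self.n_species)]

    def _per_locus(self, value: float | Mapping[str, float], locus: str) -> float:
        if isinstance(value, Mapping):
            return float(value[locus])
        return float(value)

    def inter_for(self, locus: str) -> float:
        return self._per_locus(self.inter_divergence, locus)

    def intra_for(self, locus: str) -> float:
        return self._per_locus(self.intra_divergence, locus)

    def accessions_for(self, species: str) -> int:
        if isinstance(self.accessions_per_species, Mapping):
            return int(self.accessions_per_species[species])
        return int(self.accessions_per_species)

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not self.loci:
            raise ValueError("need at least one locus")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        labels = set(self.species_labels())
        for locus in self.loci:
            if self.inter_for(locus.name) < 0 or self.intra_for(locus.name) < 0:
                raise ValueError("divergences must be non-negative")
        for a, b in self.plastid_capture_pairs:
            if a not in labels or b not in labels:
                raise ValueError(f"capture pair ({a}, {b}) references unknown species")
            if a == b:
                raise ValueError("capture pair must join two distinct species")
        for sp, missing in self.missing_loci.items():
            if sp not in labels:
                raise ValueError(f"missing_loci references unknown species {sp!r}")
            unknown = set(missing) - set(names)
            if unknown:
                raise ValueError(f"missing_loci for {sp!r}: unknown loci {sorted(unknown)}")
        for sp in labels:
            if self.accessions_for(sp) < 1:
                raise ValueError(f"species {sp!r} needs at least 1 accession")


def k2p_transition_probs(divergence: float, kappa: float) -> tuple[float, float, float]:
    """Exact per-site K2P substitution probabilities for a branch.

    Returns (p_same, p_transition, p_each_transversion) for a branch of
    ``divergence`` expected substitutions/site with transition:transversion
    rate ratio ``kappa`` (each of the two transversion targets gets
    ``p_each_transversion``).  Derived from the K2P spectral solution with
    alpha*t = kappa*d/(kappa+2) and beta*t = d/(kappa+2).
    """
    if divergence < 0:
        raise ValueError("divergence must be non-negative")
    if divergence == 0:
        return 1.0, 0.0, 0.0
    bt = divergence / (kappa + 2.0)
    e1 = np.exp(-4.0 * bt)  # exp(-4 beta t)
    e2 = np.exp(-2.0 * (kappa + 1.0) * bt)  # exp(-2 (alpha+beta) t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # per transversion target
    p_same = 1.0 - p_ts - 2.0 * p_tv
    return float(p_same), float(p_ts), float(p_tv)


def evolve_sequence(
    parent: str | np.ndarray,
    branch_divergence: float,
    kappa: float,
    rng: np.random.Generator,
) -> str | np.ndarray:
    """Evolve a sequence along one branch of the K2P process.

    Site fates are i.i.d. draws from the exact transition-probability
    matrix, so the expected realized (corrected) divergence equals
    ``branch_divergence`` at any branch length, not only in the short-
    branch limit.  Input and output types match (str in, str out).
    """
    as_str = isinstance(parent, str)
    codes = encode_sequence(parent).copy()
    if (codes > 3).any():
        raise ValueError("parent sequence must be over A, C, G, T only")
    p_same, p_ts, p_tv = k2p_transition_probs(branch_divergence, kappa)
    if branch_divergence > 0:
        # fate per site: 0 = unchanged, 2 = transition partner (code^2),
        # 1 and 3 = the two transversion partners (code^1, code^3)
        fate = rng.choice(
            np.array([0, 2, 1, 3], dtype=np.uint8),
            size=codes.size,
            p=[p_same, p_ts, p_tv, p_tv],
        )
        codes ^= fate
    if as_str:
        return "".join(_DECODE[codes])
    return codes


@dataclass
class GenusTruth:
    """Ground truth implied by the realized founder haplotypes.

    ``zero_distance_pairs`` maps each locus to the set of species pairs
    whose founders are byte-identical there — exactly the pairs a
    zero-threshold analysis must report unresolved when intra-specific
    noise is zero.  Capture pairs always appear in every plastid locus's
    set; additional coincidental pairs can arise at low configured
    divergence, as in real congeneric genera.
    """

    species: tuple[str, ...]
    accessions: dict[str, tuple[str, ...]]  # species -> accession ids
    zero_distance_pairs: dict[str, frozenset[frozenset[str]]]
    species_at_locus: dict[str, tuple[str, ...]]

    def expected_unresolved(self, member_loci: Sequence[str]) -> frozenset[frozenset[str]]:
        """Pairs unresolved under a concatenation: zero-distance in every member.

        Restricted to species carrying all member loci.
        """
        members = list(member_loci)
        common = set(self.species_at_locus[members[0]])
        for l in members[1:]:
            common &= set(self.species_at_locus[l])
        out = self.zero_distance_pairs[members[0]]
        for l in members[1:]:
            out = out & self.zero_distance_pairs[l]
        return frozenset(p for p in out if p <= common)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "species": list(self.species),
            "accessions": {s: list(a) for s, a in self.accessions.items()},
            "zero_distance_pairs": {
                locus: sorted(sorted(p) for p in pairs)
                for locus, pairs in self.zero_distance_pairs.items()
            },
            "species_at_locus": {l: list(s) for l, s in self.species_at_locus.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def simulate_genus(cfg: SimulationConfig) -> tuple[BarcodeDataset, GenusTruth]:
    """Generate one congeneric genus dataset plus its ground truth.

    Deterministic under a fixed config (byte-identical datasets across
    runs with the same seed).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    species = cfg.species_labels()
    capture = [(a, b) for a, b in cfg.plastid_capture_pairs]

    alignments: list[LocusAlignment] = []
    sheet_rows: list[dict[str, str]] = []
    zero_pairs: dict[str, frozenset[frozenset[str]]] = {}
    species_at_locus: dict[str, tuple[str, ...]] = {}
    accessions: dict[str, tuple[str, ...]] = {
        sp: tuple(
            f"{sp}.acc{j + 1}" for j in range(cfg.accessions_for(sp))
        )
        for sp in species
    }

    for locus in cfg.loci:
        ancestor = rng.integers(0, 4, size=locus.length).astype(np.uint8)
        half_inter = cfg.inter_for(locus.name) / 2.0
        half_intra = cfg.intra_for(locus.name) / 2.0

        founders: dict[str, np.ndarray] = {}
        for sp in species:
            founders[sp] = np.asarray(
                evolve_sequence(ancestor, half_inter, cfg.kappa, rng)
            )
        if locus.genome == "plastid":
            for donor, receiver in capture:
                founders[receiver] = founders[donor].copy()

        present = [
            sp for sp in species if locus.name not in cfg.missing_loci.get(sp, ())
        ]
        species_at_locus[locus.name] = tuple(present)

        records = []
        for sp in present:
            for acc in accessions[sp]:
                child = evolve_sequence(founders[sp], half_intra, cfg.kappa, rng)
                seq = "".join(_DECODE[np.asarray(child)])
                records.append(
                    AlignedRecord(accession_id=acc, sequence=seq, species_label=sp)
                )
                sheet_rows.append(
                    {
                        "accession_id": acc,
                        "species_label": sp,
                        "locus_name": locus.name,
                        "source_tag": "self",
                    }
                )
        alignments.append(LocusAlignment(locus_name=locus.name, records=tuple(records)))

        pairs = set()
        for i, a in enumerate(present):
            for b in present[i + 1 :]:
                if np.array_equal(founders[a], founders[b]):
                    pairs.add(frozenset((a, b)))
        zero_pairs[locus.name] = frozenset(pairs)

    import pandas as pd

    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    ds = build_dataset(alignments, sheet)
    truth = GenusTruth(
        species=tuple(species),
        accessions=accessions,
        zero_distance_pairs=zero_pairs,
        species_at_locus=species_at_locus,
    )
    return ds, truth


def dendrobium_like_config(seed: int) -> SimulationConfig:
    """Default study conditions: a 36-species orchid-like genus.

    33 species carry multiple accessions (25 with 9 and 8 with 8, i.e.
    289 accessions) and 3 are singletons, 292 accessions in all.  Five
    loci: the nuclear ribosomal ITS plus four plastid coding loci, with
    per-locus expected inter-specific divergences at the values typical
    of a congeneric orchid genus (nuclear an order of magnitude above
    plastid), intra-specific divergence ~0.005 for ITS, trace for matK
    and zero for the other plastid loci, and one species pair sharing an
    identical plastid haplotype across every plastid locus.
    """
    n_species = 36
    width = len(str(n_species))
    labels = [f"species_{i + 1:0{width}d}" for i in range(n_species)]
    acc: dict[str, int] = {}
    for i, sp in enumerate(labels):
        if i < 25:
            acc[sp] = 9
        elif i < 33:
            acc[sp] = 8
        else:
            acc[sp] = 1  # singletons, excluded from intra statistics
    return SimulationConfig(
        n_species=n_species,
        accessions_per_species=acc,
        loci=[
            LocusModel("ITS", 620, "nuclear"),
            LocusModel("matK", 780, "plastid"),
            LocusModel("rbcL", 550, "plastid"),
            LocusModel("rpoB", 470, "plastid"),
            LocusModel("rpoC1", 480, "plastid"),
        ],
        kappa=2.0,
        inter_divergence={
            "ITS": 0.1714,
            "matK": 0.0126,
            "rbcL": 0.0061,
            "rpoB": 0.0077,
            "rpoC1": 0.0042,
        },
        intra_divergence={
            "ITS": 0.005,
            "matK": 0.0008,
            "rbcL": 0.0,
            "rpoB": 0.0,
            "rpoC1": 0.0,
        },
        plastid_capture_pairs=[("species_01", "species_02")],
        seed=seed,
    )
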