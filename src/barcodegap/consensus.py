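"""Per-species consensus representatives.

Each species' accessions at a locus are collapsed into a single
representative by column-wise strict majority.  Ties between bases are
recorded as the minimal IUPAC ambiguity code covering the tied bases,
which downstream distance computation then skips (pairwise deletion);
this keeps the representative deterministic and order-invariant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import AlignedRecord, BarcodeDataset, LocusAlignment

__all__ = [
    "SpeciesProfile",
    "consensus_representative",
    "build_species_profiles",
    "representatives_for_locus",
    "write_representatives",
]

# minimal IUPAC code for each non-empty subset of {A,C,G,T}
IUPAC_FOR_SET = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

_BASES = set("ACGT")


def _consensus_column(chars: Sequence[str]) -> str:
    """Consensus of one alignment column.

    Only canonical bases and the gap character vote; everything else
    (N, ?, ambiguity codes) is missing and ignored.  A base or gap wins
    outright on strict majority of the votes; otherwise the tied (or
    plurality) bases collapse to an IUPAC code.  A column with no votes
    at all is 'N'.
    """
    counts = Counter(c for c in chars if c in _BASES or c == "-")
    total = sum(counts.values())
    if total == 0:
        return "N"
    top, top_count = counts.most_common(1)[0]
    if top_count * 2 > total:
        if top == "-":
            return "-"
        return top
    base_counts = {b: n for b, n in counts.items() if b in _BASES}
    if not base_counts:  # only gaps, but not a strict majority: cannot happen
        return "-"
    best = max(base_counts.values())
    tied = frozenset(b for b, n in base_counts.items() if n == best)
    return IUPAC_FOR_SET[tied]


def consensus_representative(records: Iterable[AlignedRecord | str]) -> str:
    """Column-wise majority consensus of one species' aligned accessions.

    Accepts aligned records or plain sequences.  A single sequence is
    returned unchanged; the result is invariant to record order and
    idempotent (consensus of the consensus is itself).
    """
    seqs = [r.sequence if isinstance(r, AlignedRecord) else r for r in records]
    if not seqs:
        raise ValueError("consensus of zero records")
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("consensus requires equal-length aligned sequences")
    if len(seqs) == 1:
        return seqs[0]
    return "".join(_consensus_column(col) for col in zip(*seqs))


@dataclass
class SpeciesProfile:
    """One species' representative sequence per locus it was sampled for."""

    species_label: str
    representatives: dict[str, str] = field(default_factory=dict)
    n_accessions: dict[str, int] = field(default_factory=dict)

    def loci(self) -> tuple[str, ...]:
        return tuple(self.representatives)


def build_species_profiles(ds: BarcodeDataset) -> dict[str, SpeciesProfile]:
    """One profile per species, with a representative for each locus sampled.

    Species lacking a locus simply have no representative for it;
    intra-specific statistics stay at accession level and never use these.
    """
    profiles: dict[str, SpeciesProfile] = {}
    for locus_name, aln in ds.loci.items():
        for label, recs in aln.by_species().items():
            prof = profiles.setdefault(label, SpeciesProfile(species_label=label))
            prof.representatives[locus_name] = consensus_representative(recs)
            prof.n_accessions[locus_name] = len(recs)
    return profiles


def representatives_for_locus(
    profiles: Mapping[str, SpeciesProfile], locus_name: str
) -> dict[str, str]:
    """species label → representative sequence, for species carrying the locus."""
    return {
        label: prof.representatives[locus_name]
        for label, prof in profiles.items()
        if locus_name in prof.representatives
    }


def write_representatives(
    profiles: Mapping[str, SpeciesProfile], locus_name: str, path: str | Path
) -> None:
    """Export one locus' representatives as multi-FASTA, species labels as headers."""
    reps = representatives_for_locus(profiles, locus_name)
    with open(path, "w") as fh:
        for label, seq in reps.items():
            fh.write(f">{label}\n{seq}\n")
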