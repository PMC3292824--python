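"""Publication-style table rendering for analysis bundles.

Rendering is a pure function of the bundle: the same bundle always
produces byte-identical files.  Distances are printed to 4 decimals and
percentages to 2 (half-up).
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .resolution import AnalysisBundle, round_half_up

__all__ = [
    "divergence_table",
    "resolution_table",
    "unresolved_pairs_table",
    "resolution_by_scope_table",
    "render_reports",
]

_D = 4  # distance decimals


def _fmt_dist(x: float) -> str:
    return "NA" if (x is None or math.isnan(x)) else f"{round_half_up(x, _D):.{_D}f}"


def divergence_table(bundle: AnalysisBundle) -> pd.DataFrame:
    """Intra/inter divergence summary, one row per scope (mirrors a
    candidate-locus divergence table)."""
    rows = []
    for sid, div in bundle.divergence.items():
        rows.append(
            {
                "scope": sid,
                "n_species_intra": div.n_species_intra,
                "intra_range": f"{_fmt_dist(div.intra_min)} - {_fmt_dist(div.intra_max)}",
                "n_species_inter": div.n_species_inter,
                "inter_mean": _fmt_dist(div.inter_mean),
                "inter_range": f"{_fmt_dist(div.inter_min)} - {_fmt_dist(div.inter_max)}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scope",
            "n_species_intra",
            "intra_range",
            "n_species_inter",
            "inter_mean",
            "inter_range",
        ],
    )


def resolution_table(bundle: AnalysisBundle, scopes: list[str] | None = None) -> pd.DataFrame:
    """Per-scope resolution: A, unresolved pairs, B, C and the percent."""
    rows = []
    for sid, res in bundle.resolution.items():
        if scopes is not None and sid not in scopes:
            continue
        rows.append(
            {
                "scope": sid,
                "n_species_analyzed_A": res.A,
                "n_unresolved_pairs": res.n_unresolved_pairs,
                "n_species_unresolved_B": res.B,
                "n_species_discriminated_C": res.C,
                "percent_resolution": f"{res.percent:.2f}",
                "tau": _fmt_dist(res.tau),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scope",
            "n_species_analyzed_A",
            "n_unresolved_pairs",
            "n_species_unresolved_B",
            "n_species_discriminated_C",
            "percent_resolution",
            "tau",
        ],
    )


def unresolved_pairs_table(bundle: AnalysisBundle) -> pd.DataFrame:
    rows = [
        {"scope": sid, "species_a": a, "species_b": b}
        for sid, res in bundle.resolution.items()
        for a, b in res.unresolved_pairs
    ]
    return pd.DataFrame(rows, columns=["scope", "species_a", "species_b"])


def resolution_by_scope_table(bundle: AnalysisBundle) -> pd.DataFrame:
    """Scope → percent, the tabular stand-in for a resolution bar chart."""
    rows = [
        {"scope": sid, "percent_resolution": f"{res.percent:.2f}"}
        for sid, res in bundle.resolution.items()
    ]
    return pd.DataFrame(rows, columns=["scope", "percent_resolution"])


def render_reports(bundle: AnalysisBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the TSV tables and the JSON bundle into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    locus_scopes = [s for s in bundle.resolution if "+" not in s]
    combo_scopes = [s for s in bundle.resolution if "+" in s]
    paths = {
        "divergence": out_dir / "divergence.tsv",
        "resolution_loci": out_dir / "resolution_loci.tsv",
        "resolution_combos": out_dir / "resolution_combos.tsv",
        "unresolved_pairs": out_dir / "unresolved_pairs.tsv",
        "resolution_by_scope": out_dir / "resolution_by_scope.tsv",
        "bundle": out_dir / "bundle.json",
    }
    divergence_table(bundle).to_csv(paths["divergence"], sep="\t", index=False)
    resolution_table(bundle, locus_scopes).to_csv(
        paths["resolution_loci"], sep="\t", index=False
    )
    resolution_table(bundle, combo_scopes).to_csv(
        paths["resolution_combos"], sep="\t", index=False
    )
    unresolved_pairs_table(bundle).to_csv(
        paths["unresolved_pairs"], sep="\t", index=False
    )
    resolution_by_scope_table(bundle).to_csv(
        paths["resolution_by_scope"], sep="\t", index=False
    )
    bundle.to_json(paths["bundle"])
    return paths
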