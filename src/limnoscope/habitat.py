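"""Taxa-habitat association profiling from relative-abundance tables.

A "valid match" is one (sample, taxon) row whose relative abundance meets
the inclusive threshold (default 0.5 %); one sample can contribute one
match per taxon. Habitat shares are match fractions per habitat; peak
abundance is the maximum abundance the taxon reaches in each habitat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass
class HabitatSummary:
    taxon: str
    n_valid_matches: int
    habitat_share: dict[str, float]     # percent, sums to 100
    peak_abundance: dict[str, float]    # percent, max per habitat


def filter_valid_matches(
    table: pd.DataFrame, threshold_pct: float = 0.5
) -> pd.DataFrame:
    """Keep rows with abundance >= threshold (inclusive comparison)."""
    return table[table["rel_abundance_pct"] >= threshold_pct].copy()


def summarize_taxon(table_valid: pd.DataFrame, taxon: str) -> HabitatSummary | None:
    """Habitat shares and peak abundances for one taxon over valid matches.

    Returns None (with a warning) when the taxon has no valid match.
    """
    sub = table_valid[table_valid["taxon"] == taxon]
    if len(sub) == 0:
        warnings.warn(f"taxon {taxon!r}: no valid matches; summary missing")
        return None
    counts = sub.groupby("habitat")["rel_abundance_pct"].agg(["count", "max"])
    total = int(counts["count"].sum())
    return HabitatSummary(
        taxon=taxon,
        n_valid_matches=total,
        habitat_share={
            h: 100.0 * c / total for h, c in counts["count"].items()
        },
        peak_abundance={h: float(m) for h, m in counts["max"].items()},
    )


def summarize_all(table_valid: pd.DataFrame) -> pd.DataFrame:
    """One row per (taxon, habitat): share and peak abundance."""
    rows = []
    for taxon in sorted(table_valid["taxon"].unique()):
        summary = summarize_taxon(table_valid, taxon)
        if summary is None:
            continue
        for habitat, share in sorted(summary.habitat_share.items()):
            rows.append(
                {
                    "taxon": taxon,
                    "habitat": habitat,
                    "n_valid_matches": summary.n_valid_matches,
                    "habitat_share_pct": share,
                    "peak_abundance_pct": summary.peak_abundance[habitat],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "taxon", "habitat", "n_valid_matches",
            "habitat_share_pct", "peak_abundance_pct",
        ],
    )
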