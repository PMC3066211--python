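"""Gene-level hit calling by top-k / >=m-of-r siRNA concordance.

A gene is called a hit when at least ``m`` of its ``r`` independent siRNAs
rank inside the top ``k`` summarized z-scores (reduction-positive), the
standard guard against single-siRNA off-target phenotypes.  siRNAs whose
cell-density z exceeds a threshold are treated as viability confounds and,
by default, removed from candidacy *before* the top-k selection ("without
affecting cell density").  The same machinery applied to the density
channel alone yields the single-channel cell-density hit analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen_model import ScreenConfig, SiRNALibrary, ValidationError
from .scoring import NormalizedScreen

__all__ = [
    "HitTable",
    "rank_sirnas",
    "viability_filter",
    "call_gene_hits",
    "single_channel_hit_analysis",
    "density_hit_analysis",
    "hit_rate_percent",
]


def hit_rate_percent(n_hits: int, n_genes: int) -> int:
    """Hit rate as nearest-integer percent: round(100 * hits / genes)."""
    if n_genes <= 0:
        raise ValidationError("n_genes must be positive")
    return int(round(100.0 * n_hits / n_genes))


@dataclass
class HitTable:
    """Gene-level calls under the top-k / >=m-of-r concordance rule.

    ``table`` has one row per gene, sorted by descending mean z: gene, mean z
    over its scored siRNAs, per-siRNA z and ranks, count of (unflagged)
    siRNAs in the top k, the hit flag, and a viability flag (any siRNA with
    |z_MB| >= threshold).  ``hit_rate`` is the nearest-integer percentage of
    genes called.
    """

    table: pd.DataFrame
    top_k: int
    min_concordant: int
    direction: str = "reduction"
    channel: str = "EROD"
    incomplete_genes: list = field(default_factory=list)

    @property
    def hit_genes(self) -> list[str]:
        return list(self.table.loc[self.table["hit"], "gene"])

    @property
    def n_hits(self) -> int:
        return int(self.table["hit"].sum())

    @property
    def n_genes(self) -> int:
        return int(len(self.table))

    @property
    def hit_rate(self) -> int:
        return hit_rate_percent(self.n_hits, self.n_genes)


def rank_sirnas(
    summary: pd.DataFrame,
    top_k: int,
    direction: str = "reduction",
    z_column: str = "z_erod",
) -> pd.DataFrame:
    """Rank siRNAs by summarized z, flagging the top-k set.

    Reduction-positive z sorts descending; ``direction="increase"`` reverses
    the sign of interest.  Ties (including at the k-th rank) break
    lexicographically by siRNA identifier, keeping the selection
    deterministic instead of inflating k.  Unscored (NaN) siRNAs rank last
    and are never in the top k.
    """
    df = summary.copy()
    key = df[z_column] if direction == "reduction" else -df[z_column]
    df["_key"] = key
    n_scored = int(df["_key"].notna().sum())
    if n_scored < top_k:
        warnings.warn(
            f"only {n_scored} scored siRNAs for top_k={top_k}; flagging all",
            stacklevel=2,
        )
    df = df.sort_values(
        ["_key", "sirna"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["in_top_k"] = (df["rank"] <= top_k) & df["_key"].notna()
    return df.drop(columns="_key")


def viability_filter(summary: pd.DataFrame, threshold: float) -> pd.Series:
    """Flag siRNAs whose density z magnitude reaches the threshold.

    Flagged siRNAs are viability confounds: their apparent pathway effect
    cannot be separated from a change in cell number.  NaN density z is not
    flagged (no evidence of a confound).
    """
    z_mb = summary["z_mb"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        flags = np.abs(z_mb) >= threshold
    flags[~np.isfinite(z_mb)] = False
    return pd.Series(flags, index=summary.index, name="viability_flagged")


def call_gene_hits(
    summary: pd.DataFrame,
    library: SiRNALibrary,
    config: ScreenConfig | None = None,
    z_column: str = "z_erod",
    apply_viability_filter: bool = True,
) -> HitTable:
    """Apply the full concordance rule to a per-siRNA summary table.

    ``summary`` needs columns ``sirna``, ``gene``, ``z_column`` and (when
    the viability filter is on) ``z_mb``.  Flagged siRNAs are removed from
    candidacy before ranking by default (``config.viability_filter_before_
    ranking``); the alternative order ranks first and then discards flagged
    members of the top k.
    """
    config = config or ScreenConfig()
    df = summary.copy().reset_index(drop=True)
    if apply_viability_filter and np.isfinite(config.viability_z_threshold):
        flags = viability_filter(df, config.viability_z_threshold)
    else:
        flags = pd.Series(False, index=df.index, name="viability_flagged")
    df["viability_flagged"] = flags.to_numpy()

    if config.viability_filter_before_ranking:
        candidates = df[~df["viability_flagged"]]
        ranked = rank_sirnas(candidates, config.top_k, config.direction, z_column)
        ranked = pd.concat(
            [ranked, df[df["viability_flagged"]].assign(rank=np.nan, in_top_k=False)],
            ignore_index=True,
        )
    else:
        ranked = rank_sirnas(df, config.top_k, config.direction, z_column)
        ranked.loc[ranked["viability_flagged"], "in_top_k"] = False

    lib_counts = library.entries.groupby("gene")["sirna"].count()
    incomplete: list[str] = []
    rows = []
    for gene, grp in ranked.groupby("gene"):
        grp = grp.sort_values("sirna")
        z_vals = grp[z_column].to_numpy(dtype=float)
        n_scored = int(np.isfinite(z_vals).sum())
        expected = int(lib_counts.get(gene, config.sirnas_per_gene))
        if n_scored != expected or expected != config.sirnas_per_gene:
            incomplete.append(gene)
        n_in_top = int(grp["in_top_k"].sum())
        mean_z = float(np.nanmean(z_vals)) if n_scored else float("nan")
        rows.append(
            {
                "gene": gene,
                "mean_z": mean_z,
                "n_sirnas_scored": n_scored,
                "n_in_top_k": n_in_top,
                "hit": n_in_top >= config.min_concordant,
                "viability_flagged": bool(grp["viability_flagged"].any()),
                "sirna_z": ";".join(
                    f"{s}={z:.4g}" if np.isfinite(z) else f"{s}=NA"
                    for s, z in zip(grp["sirna"], z_vals)
                ),
                "sirna_ranks": ";".join(
                    str(int(r)) if np.isfinite(r) else "NA" for r in grp["rank"]
                ),
            }
        )
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} gene(s) without a complete set of scored siRNAs; "
            "concordance applied to available siRNAs",
            stacklevel=2,
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["mean_z", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return HitTable(
        table=table,
        top_k=config.top_k,
        min_concordant=config.min_concordant,
        direction=config.direction,
        incomplete_genes=incomplete,
    )


def single_channel_hit_analysis(
    norm: NormalizedScreen,
    library: SiRNALibrary,
    config: ScreenConfig | None = None,
    z_column: str = "z_mb",
) -> HitTable:
    """Apply the identical top-k/>=m-of-r machinery to a single channel."""
    config = config or ScreenConfig()
    ht = call_gene_hits(
        norm.sirna_summary,
        library,
        config,
        z_column=z_column,
        apply_viability_filter=False,
    )
    ht.channel = "MB" if z_column == "z_mb" else "EROD"
    return ht


def density_hit_analysis(
    norm: NormalizedScreen,
    library: SiRNALibrary,
    config: ScreenConfig | None = None,
) -> HitTable:
    """Cell-density hit calling: which genes' knock-down reduces cell number.

    Runs the same concordance rule on the MB-channel z-scores alone
    (direction = reduction of density); no viability filter applies since
    density *is* the phenotype here.
    """
    return single_channel_hit_analysis(norm, library, config, z_column="z_mb")
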