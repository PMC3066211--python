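"""Two-channel preprocessing: normalize -> ratio -> score -> robust z.

The scoring path mirrors the standard two-channel workflow for cell-based
RNAi screens.  Per plate and channel, raw values are normalized (division by
the plate's sample-well median by default, or expressed as a percentage of
the negative-control mean for control QC).  The per-well EROD/MB ratio then
cancels viability effects: a siRNA that merely kills cells lowers both
channels proportionally and keeps the ratio at baseline, so only genuine
pathway effects move it.  Because channel-wise medians leave a residual
per-plate factor in the ratio, the ratio is re-centered by the plate median
of sample-well ratios before scores are pooled; this makes the score exactly
invariant both to rescaling a whole plate and to rescaling both channels of
any single well.  Scores (log2 ratio by default) are converted to robust
z-scores per replicate — (median - x) / (1.4826 * MAD) over all sample wells
of the replicate, so pathway *reduction* is positive — and finally averaged
over replicates per siRNA.

The same machinery applied to the MB channel alone yields cell-density
z-scores, used both for the viability filter and for the single-channel
density hit analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen_model import (
    DegenerateDispersionError,
    DegenerateTraceError,
    NormalizationError,
    PlateLayout,
    ROLE_EMPTY,
    ROLE_SAMPLE,
    ScreenConfig,
    ScreenDataset,
    SiRNALibrary,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "EXCLUDE_LOW_VIABILITY",
    "EXCLUDE_MISSING",
    "erod_slope",
    "reduce_kinetic_traces",
    "percent_of_neg_controls",
    "plate_median_normalize",
    "channel_ratio",
    "robust_z",
    "robust_z_scores",
    "summarize_replicates",
    "NormalizedScreen",
    "score_screen",
    "replicate_correlation",
    "qq_export",
    "PlateImage",
    "plate_image_export",
]

EXCLUDE_LOW_VIABILITY = "low_viability_signal"
EXCLUDE_MISSING = "missing_value"


# ---------------------------------------------------------------------------
# Kinetic traces
# ---------------------------------------------------------------------------

def erod_slope(trace: Sequence[tuple[float, float]] | np.ndarray) -> float:
    """OLS slope of fluorescence against time (fluorescence units / min).

    The kinetic EROD assay reads resorufin fluorescence repeatedly over a
    15-minute window; the activity is the ordinary-least-squares slope over
    all points.  Requires >= 2 distinct time points.
    """
    arr = np.asarray(trace, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateTraceError("trace needs >= 2 (time, fluorescence) points")
    t, f = arr[:, 0], arr[:, 1]
    if np.unique(t).size < 2:
        raise DegenerateTraceError("all trace time points are equal")
    tbar, fbar = t.mean(), f.mean()
    return float(((t - tbar) * (f - fbar)).sum() / ((t - tbar) ** 2).sum())


def reduce_kinetic_traces(screen: ScreenDataset) -> ScreenDataset:
    """Replace/insert EROD values computed from kinetic traces.

    Traces take precedence over any precomputed EROD activity for the same
    well.  Negative fitted slopes are clipped at 0 (an activity readout
    cannot be negative; a slightly negative fit is measurement noise).
    """
    if not screen.traces:
        return screen
    df = screen.values
    keyed = {(r, p, w): i
             for i, (r, p, w, c) in enumerate(
                 zip(df["replicate"], df["plate"], df["well"], df["channel"]))
             if c == "EROD"}
    rows = []
    values = df["value"].to_numpy().copy()
    for (rep, plate, well), trace in screen.traces.items():
        slope = max(erod_slope(trace), 0.0)
        if (rep, plate, well) in keyed:
            values[keyed[(rep, plate, well)]] = slope
        else:
            rows.append({"replicate": rep, "plate": plate, "well": well,
                         "channel": "EROD", "value": slope})
    out = df.copy()
    out["value"] = values
    if rows:
        out = pd.concat([out, pd.DataFrame(rows)], ignore_index=True)
    return ScreenDataset(values=out, traces={})


# ---------------------------------------------------------------------------
# Plate normalization
# ---------------------------------------------------------------------------

def percent_of_neg_controls(
    plate_values: Mapping[str, float],
    layout: PlateLayout,
) -> dict[str, float]:
    """Express each well as a percentage of the negative-control mean.

    The mean of the plate's (non-missing) negative-control wells is set at
    100%; every well is reported relative to it.
    """
    controls = [
        plate_values[w]
        for w in layout.neg_control_wells
        if w in plate_values and np.isfinite(plate_values[w])
    ]
    if not controls:
        raise NormalizationError("no non-missing negative controls on plate")
    center = float(np.mean(controls))
    if center <= 0:
        raise NormalizationError(f"negative-control mean {center} is not positive")
    return {w: 100.0 * v / center for w, v in plate_values.items()}


def plate_median_normalize(
    plate_values: Mapping[str, float],
    layout: PlateLayout,
    sample_wells: Sequence[str] | None = None,
) -> dict[str, float]:
    """Divide every well by the median of the plate's sample wells.

    ``sample_wells`` restricts the median to the wells actually carrying
    library siRNAs on this plate (a sample-role well unused on a plate is
    ignored).  The sample-well median of the output is exactly 1.
    """
    if sample_wells is None:
        sample_wells = layout.sample_wells
    samples = [
        plate_values[w]
        for w in sample_wells
        if w in plate_values and np.isfinite(plate_values[w])
    ]
    if len(samples) < 3:
        raise NormalizationError("need >= 3 non-missing sample wells on plate")
    center = float(np.median(samples))
    if center <= 0:
        raise NormalizationError(f"sample-well median {center} is not positive")
    return {w: v / center for w, v in plate_values.items()}


def channel_ratio(norm_erod: float, norm_mb: float, mb_floor: float):
    """Normalized EROD / normalized MB, or an exclusion marker.

    Wells whose normalized cell-density signal falls below ``mb_floor``
    carry no interpretable activity reading; they are excluded (a value,
    not an exception) with reason ``low_viability_signal``.
    """
    if not np.isfinite(norm_mb) or norm_mb < mb_floor:
        return EXCLUDE_LOW_VIABILITY
    return float(norm_erod) / float(norm_mb)


# ---------------------------------------------------------------------------
# Robust z-scores
# ---------------------------------------------------------------------------

def _median_mad(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, mad


def robust_z(
    sample_values: Sequence[float],
    x: float,
    direction: str = "reduction",
    consistency: float = 1.4826,
) -> float:
    """Robust z of ``x`` against ``sample_values``: (median - x) / (c * MAD).

    With ``direction="reduction"`` a value *below* the sample median scores
    positive, so pathway-reducing siRNAs get positive z.  Raises on MAD = 0.
    """
    vals = np.asarray(sample_values, dtype=float)
    if vals.size < 3:
        raise ValidationError("robust_z needs >= 3 sample values")
    med, mad = _median_mad(vals)
    if mad == 0:
        raise DegenerateDispersionError("MAD of sample values is 0")
    z = (med - float(x)) / (consistency * mad)
    return z if direction == "reduction" else -z


def robust_z_scores(
    values: np.ndarray,
    direction: str = "reduction",
    consistency: float = 1.4826,
    scale_fallback: bool = False,
) -> np.ndarray:
    """Vectorized robust z of every element against the whole vector.

    With ``scale_fallback`` (pipeline behaviour for degenerate inputs), a
    zero MAD falls back to the standard deviation; only when that is also
    zero — every score identical — is DegenerateDispersionError raised.
    """
    vals = np.asarray(values, dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size < 3:
        raise ValidationError("need >= 3 finite scores for z computation")
    med, mad = _median_mad(finite)
    scale = consistency * mad
    if scale == 0:
        if not scale_fallback:
            raise DegenerateDispersionError("MAD of scores is 0")
        scale = float(np.std(finite))
        if scale == 0:
            raise DegenerateDispersionError("all scores identical; z undefined")
    z = (med - vals) / scale
    return z if direction == "reduction" else -z


def summarize_replicates(z_values: Sequence[float]) -> tuple[float, int]:
    """Mean over non-missing replicate z-scores, with the count used.

    Returns (nan, 0) when every replicate is missing, marking the siRNA
    missing rather than raising: exclusions are data, not errors, at this
    stage.
    """
    vals = np.asarray(z_values, dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return float("nan"), 0
    return float(finite.mean()), int(finite.size)


# ---------------------------------------------------------------------------
# Whole-screen scoring
# ---------------------------------------------------------------------------

@dataclass
class NormalizedScreen:
    """All per-well and per-siRNA quantities derived from one screen.

    wells
        One row per (replicate, plate, well): role, siRNA/gene, raw and
        normalized channel values, EROD/MB ratio, re-centered score, the MB
        score, and an exclusion flag with reason.
    sirna_replicate_z
        Per-siRNA, per-replicate robust z for the EROD-ratio score
        (``z_erod``) and the MB-only score (``z_mb``).
    sirna_summary
        Per-siRNA replicate-mean z for both channels with replicate counts.
    """

    wells: pd.DataFrame
    sirna_replicate_z: pd.DataFrame
    sirna_summary: pd.DataFrame
    config: ScreenConfig = field(default_factory=ScreenConfig)
    exclusion_counts: dict = field(default_factory=dict)


def _score_transform(values: np.ndarray, log_scale: bool) -> np.ndarray:
    if log_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(values)
    return values


def score_screen(
    screen: ScreenDataset,
    layout: PlateLayout,
    library: SiRNALibrary,
    config: ScreenConfig | None = None,
) -> NormalizedScreen:
    """Run the full two-channel preprocessing on a screen.

    Stages: reduce kinetic traces -> per-plate per-channel normalization ->
    per-well EROD/MB ratio with viability floor -> per-plate ratio
    re-centering -> per-replicate robust z over pooled sample scores ->
    replicate mean per siRNA.  MB-only z-scores are computed alongside on
    the normalized MB channel.
    """
    config = config or ScreenConfig()
    screen = reduce_kinetic_traces(screen)
    wide = screen.wide()

    wide["role"] = wide["well"].map(layout.role_map).fillna(ROLE_EMPTY)
    lib = library.entries.rename(columns={"well": "well", "plate": "plate"})
    wide = wide.merge(
        lib[["plate", "well", "sirna", "gene"]], on=["plate", "well"], how="left"
    )
    # Sample-role wells without library content are unused on that plate.
    unused = (wide["role"] == ROLE_SAMPLE) & wide["sirna"].isna()
    wide.loc[unused, "role"] = ROLE_EMPTY
    wide = wide[wide["role"] != ROLE_EMPTY].reset_index(drop=True)

    norm_e = np.full(len(wide), np.nan)
    norm_m = np.full(len(wide), np.nan)
    ratio = np.full(len(wide), np.nan)
    score = np.full(len(wide), np.nan)
    score_mb = np.full(len(wide), np.nan)
    excluded = np.zeros(len(wide), dtype=bool)
    reason = np.full(len(wide), "", dtype=object)

    is_sample = (wide["role"] == ROLE_SAMPLE).to_numpy()

    for (rep, plate), idx in wide.groupby(["replicate", "plate"]).groups.items():
        idx = np.asarray(idx)
        sub = wide.loc[idx]
        plate_vals_e = dict(zip(sub["well"], sub["EROD"]))
        plate_vals_m = dict(zip(sub["well"], sub["MB"]))
        plate_samples = list(sub.loc[sub["role"] == ROLE_SAMPLE, "well"])
        if config.normalization_method == "percent_of_neg_controls":
            ne = percent_of_neg_controls(plate_vals_e, layout)
            nm = percent_of_neg_controls(plate_vals_m, layout)
            scale = 100.0  # baseline of the normalized unit
        else:
            ne = plate_median_normalize(plate_vals_e, layout, plate_samples)
            nm = plate_median_normalize(plate_vals_m, layout, plate_samples)
            scale = 1.0
        wells_here = sub["well"].to_numpy()
        e_arr = np.array([ne[w] for w in wells_here], dtype=float)
        m_arr = np.array([nm[w] for w in wells_here], dtype=float)
        norm_e[idx] = e_arr
        norm_m[idx] = m_arr

        floor = config.mb_floor * scale
        r_arr = np.full(len(idx), np.nan)
        for j, (e, m) in enumerate(zip(e_arr, m_arr)):
            if not (np.isfinite(e) and np.isfinite(m)):
                excluded[idx[j]] = True
                reason[idx[j]] = EXCLUDE_MISSING
                continue
            val = channel_ratio(e, m, floor)
            if val == EXCLUDE_LOW_VIABILITY:
                excluded[idx[j]] = True
                reason[idx[j]] = EXCLUDE_LOW_VIABILITY
            else:
                r_arr[j] = val
        ratio[idx] = r_arr

        # Re-center the ratio by the plate median of included sample-well
        # ratios: cancels the residual per-plate factor left by channel-wise
        # normalization, making scores exactly scale-invariant.
        samp_mask = np.array(
            [wide.loc[i, "role"] == ROLE_SAMPLE and np.isfinite(ratio[i]) for i in idx]
        )
        if samp_mask.sum() >= 3:
            center = float(np.median(r_arr[samp_mask]))
            if center <= 0:
                raise NormalizationError(
                    f"plate {plate} replicate {rep}: ratio median {center} not positive"
                )
            score[idx] = _score_transform(r_arr / center, config.score_on_log_ratio)
        else:
            raise NormalizationError(
                f"plate {plate} replicate {rep}: fewer than 3 scoreable sample wells"
            )
        score_mb[idx] = _score_transform(m_arr / scale, config.score_on_log_ratio)

    wide["norm_erod"] = norm_e
    wide["norm_mb"] = norm_m
    wide["ratio"] = ratio
    wide["score"] = score
    wide["score_mb"] = score_mb
    wide["excluded"] = excluded
    wide["reason"] = reason

    # Per-replicate robust z pooled over all sample wells of the replicate.
    wide["z_erod"] = np.nan
    wide["z_mb"] = np.nan
    for rep, idx in wide.groupby("replicate").groups.items():
        idx = np.asarray(idx)
        mask = is_sample[idx] & ~excluded[idx]
        pool_idx = idx[mask]
        z = robust_z_scores(
            wide.loc[pool_idx, "score"].to_numpy(),
            direction="reduction",
            consistency=config.mad_consistency_constant,
            scale_fallback=True,
        )
        wide.loc[pool_idx, "z_erod"] = z
        mb_mask = is_sample[idx] & np.isfinite(score_mb[idx])
        mb_idx = idx[mb_mask]
        try:
            z_mb = robust_z_scores(
                wide.loc[mb_idx, "score_mb"].to_numpy(),
                direction="reduction",
                consistency=config.mad_consistency_constant,
                scale_fallback=True,
            )
            wide.loc[mb_idx, "z_mb"] = z_mb
        except DegenerateDispersionError:
            # A perfectly flat density channel (e.g. a noise-free screen
            # with no viability effects) has no z; leave it undefined so
            # the EROD analysis can still proceed.
            pass

    sample = wide[wide["role"] == ROLE_SAMPLE]
    rep_z = sample[
        ["sirna", "gene", "replicate", "plate", "well", "z_erod", "z_mb",
         "excluded", "reason"]
    ].reset_index(drop=True)

    rows = []
    for sirna, grp in rep_z.groupby("sirna"):
        z_e, n_e = summarize_replicates(grp["z_erod"])
        z_m, n_m = summarize_replicates(grp["z_mb"])
        rows.append(
            {
                "sirna": sirna,
                "gene": grp["gene"].iloc[0],
                "z_erod": z_e,
                "n_replicates_erod": n_e,
                "z_mb": z_m,
                "n_replicates_mb": n_m,
            }
        )
    summary = pd.DataFrame(rows).sort_values("sirna").reset_index(drop=True)

    counts = rep_z.loc[rep_z["excluded"], "reason"].value_counts().to_dict()
    return NormalizedScreen(
        wells=wide,
        sirna_replicate_z=rep_z,
        sirna_summary=summary,
        config=config,
        exclusion_counts=counts,
    )


# ---------------------------------------------------------------------------
# QC statistics and exports
# ---------------------------------------------------------------------------

def replicate_correlation(
    norm: NormalizedScreen, i: int, j: int, on: str = "score"
) -> float:
    """Pearson correlation of per-siRNA values between two replicates.

    ``on`` selects the quantity: ``"score"`` (log-ratio by default config),
    ``"ratio"`` or ``"z_erod"``.  Pairwise-complete over siRNAs scored in
    both replicates.
    """
    col = {"score": "score", "ratio": "ratio", "z_erod": "z_erod"}[on]
    sample = norm.wells[norm.wells["role"] == ROLE_SAMPLE]
    a = sample[sample["replicate"] == i].set_index("sirna")[col]
    b = sample[sample["replicate"] == j].set_index("sirna")[col]
    joined = pd.concat([a, b], axis=1, keys=["a", "b"]).dropna()
    if len(joined) < 3:
        raise UndefinedCorrelationError("fewer than 3 siRNAs scored in both replicates")
    if joined["a"].std() == 0 or joined["b"].std() == 0:
        raise UndefinedCorrelationError("zero variance in a replicate")
    r, _ = stats.pearsonr(joined["a"], joined["b"])
    return float(r)


def qq_export(z_values: Sequence[float]) -> pd.DataFrame:
    """Sorted observed z against standard-normal quantiles at (i - 0.5)/n."""
    vals = np.sort(np.asarray(z_values, dtype=float))
    vals = vals[np.isfinite(vals)]
    n = vals.size
    if n < 2:
        raise ValidationError("qq_export needs >= 2 values")
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"theoretical": theo, "observed": vals})


@dataclass
class PlateImage:
    """Per-plate matrix view of summarized z (rows A.., columns 1..)."""

    z: pd.DataFrame      # float matrix; NaN where no summarized z exists
    roles: pd.DataFrame  # role string per well ("sample", "neg_control", ...)


def plate_image_export(
    summary: pd.DataFrame,
    library: SiRNALibrary,
    layout: PlateLayout,
    value_column: str = "z_erod",
) -> dict[int, PlateImage]:
    """Screen-wide image matrices: one n_rows x n_cols z matrix per plate.

    Control and empty wells are marked distinctly via the companion role
    matrix (their z cells are NaN).
    """
    from .screen_model import well_name  # local to avoid cycle noise

    z_by_sirna = dict(zip(summary["sirna"], summary[value_column]))
    row_labels = [well_name(r, 0)[0] for r in range(layout.n_rows)]
    col_labels = list(range(1, layout.n_cols + 1))
    out: dict[int, PlateImage] = {}
    for plate in sorted(library.entries["plate"].unique()):
        contents = library.plate_contents(plate)
        zmat = np.full((layout.n_rows, layout.n_cols), np.nan)
        rmat = np.full((layout.n_rows, layout.n_cols), ROLE_EMPTY, dtype=object)
        for r in range(layout.n_rows):
            for c in range(layout.n_cols):
                w = well_name(r, c)
                role = layout.role(w)
                if role == ROLE_SAMPLE and w not in contents:
                    role = ROLE_EMPTY
                rmat[r, c] = role
                if role == ROLE_SAMPLE:
                    zmat[r, c] = z_by_sirna.get(contents[w], np.nan)
        out[int(plate)] = PlateImage(
            z=pd.DataFrame(zmat, index=row_labels, columns=col_labels),
            roles=pd.DataFrame(rmat, index=row_labels, columns=col_labels),
        )
    return out
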