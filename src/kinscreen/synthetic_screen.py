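"""Synthetic dual-channel screen generator with known ground truth.

Emulates the design of a kinome-wide arrayed RNAi screen: 3 replicate
experiments of 30 96-well plates carrying 712 genes x 3 siRNAs, negative
controls at A12/B12/G12/H12 and AhR-like positive controls at G1/H1 on
every plate.  The signal model is multiplicative throughout (plate readouts
are scale-type):

    EROD = base_E * plate_factor * edge * gene_effect_E * noise
    MB   = base_M * plate_factor * edge * gene_effect_M * noise'

Planted pathway ("EROD-hit") genes reduce the EROD channel only; planted
viability genes reduce both channels equally, so the EROD/MB ratio is blind
to them by construction.  Each siRNA draws its knockdown efficacy once —
an inefficient siRNA has no effect in any replicate, modelling the screen's
dominant false-negative source.  Positive controls reduce EROD only;
negative controls carry no gene effect.  Plate factors and measurement
noise are lognormal.  Identical seeds give bit-identical screens.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .screen_model import (
    DEFAULT_NEG_WELLS,
    DEFAULT_POS_WELLS,
    PlateLayout,
    ScreenDataset,
    SiRNALibrary,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_screen",
    "evaluate_recovery",
    "CLASS_EROD_HIT",
    "CLASS_VIABILITY",
    "CLASS_NULL",
]

CLASS_EROD_HIT = "erod_hit"
CLASS_VIABILITY = "viability"
CLASS_NULL = "null"


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated screen.

    Defaults reproduce the full screen geometry (712 genes x 3 siRNAs over
    3 experiments of 30 plates).  ``fraction_erod_hits`` (0.03, ~21 genes)
    matches the ~3% hit rate typical of loss-of-function screens of this
    design; ``erod_effect``/``viability_effect`` are the multiplicative
    survivals of the affected channel(s) for an efficient siRNA (0.3 = 70%
    reduction, a strong knockdown phenotype).  ``per_sirna_efficacy`` is the
    probability that a given siRNA achieves knockdown at all.  ``noise_sd``
    is the lognormal sigma of per-well measurement noise per channel,
    calibrated so that default screens show pairwise replicate correlations
    near 0.8 on the score scale; ``plate_effect_sd`` is the lognormal sigma
    of the shared per-plate factor.  ``pos_control_effect`` (0.05) makes
    positive controls abolish EROD activity without touching cell density.
    """

    seed: int = 0
    n_genes: int = 712
    sirnas_per_gene: int = 3
    n_replicates: int = 3
    n_plates: int = 30
    n_rows: int = 8
    n_cols: int = 12
    neg_wells: Sequence[str] = DEFAULT_NEG_WELLS
    pos_wells: Sequence[str] = DEFAULT_POS_WELLS
    fraction_erod_hits: float = 0.03
    erod_effect: float = 0.3
    fraction_viability_genes: float = 0.05
    viability_effect: float = 0.3
    per_sirna_efficacy: float = 0.8
    plate_effect_sd: float = 0.15
    edge_effect: float | None = None
    noise_sd: float = 0.065
    base_erod: float = 100.0
    base_mb: float = 1.0
    pos_control_effect: float = 0.05
    kinetic: bool = False
    kinetic_n_points: int = 16
    kinetic_duration_min: float = 15.0
    kinetic_baseline: float = 50.0
    shuffle_placement: bool = False

    def __post_init__(self) -> None:
        for name in ("fraction_erod_hits", "fraction_viability_genes",
                     "per_sirna_efficacy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in ("erod_effect", "viability_effect", "pos_control_effect"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name}={v} outside (0, 1]")
        for name in ("plate_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        n_hit = round(self.fraction_erod_hits * self.n_genes)
        n_via = round(self.fraction_viability_genes * self.n_genes)
        if n_hit + n_via > self.n_genes:
            raise ValidationError("hit and viability fractions exceed the gene count")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["neg_wells"] = list(data["neg_wells"])
        data["pos_wells"] = list(data["pos_wells"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class TruthTable:
    """Planted ground truth: per-gene class and per-siRNA efficacy draw."""

    genes: pd.DataFrame   # columns: gene, class
    sirnas: pd.DataFrame  # columns: sirna, gene, efficient

    def genes_of_class(self, cls: str) -> list[str]:
        return sorted(self.genes.loc[self.genes["class"] == cls, "gene"])

    def to_frame(self) -> pd.DataFrame:
        return self.sirnas.merge(self.genes, on="gene")[
            ["sirna", "gene", "class", "efficient"]
        ]

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        genes = df[["gene", "class"]].drop_duplicates().reset_index(drop=True)
        sirnas = df[["sirna", "gene", "efficient"]].copy()
        sirnas["efficient"] = sirnas["efficient"].astype(bool)
        return cls(genes=genes, sirnas=sirnas)


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Exact class counts (round(fraction * n_genes)); identities drawn."""
    genes = [f"GENE{i:04d}" for i in range(1, cfg.n_genes + 1)]
    n_hit = round(cfg.fraction_erod_hits * cfg.n_genes)
    n_via = round(cfg.fraction_viability_genes * cfg.n_genes)
    chosen = rng.choice(cfg.n_genes, size=n_hit + n_via, replace=False)
    classes = np.full(cfg.n_genes, CLASS_NULL, dtype=object)
    classes[chosen[:n_hit]] = CLASS_EROD_HIT
    classes[chosen[n_hit:]] = CLASS_VIABILITY
    return pd.DataFrame({"gene": genes, "class": classes})


def simulate_screen(
    config: SimulationConfig,
) -> tuple[ScreenDataset, PlateLayout, SiRNALibrary, TruthTable]:
    """Generate a complete screen plus its layout, library and ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    layout = PlateLayout.default(
        n_rows=cfg.n_rows, n_cols=cfg.n_cols,
        neg_wells=cfg.neg_wells, pos_wells=cfg.pos_wells,
    )
    sample_wells = layout.sample_wells
    n_sirnas = cfg.n_genes * cfg.sirnas_per_gene
    capacity = cfg.n_plates * len(sample_wells)
    if n_sirnas > capacity:
        raise ValidationError(
            f"{n_sirnas} siRNAs do not fit {cfg.n_plates} plates "
            f"x {len(sample_wells)} sample wells"
        )

    gene_classes = _assign_classes(cfg, rng)
    sirna_rows = []
    for gene in gene_classes["gene"]:
        for s in range(1, cfg.sirnas_per_gene + 1):
            sirna_rows.append({"sirna": f"{gene}_s{s}", "gene": gene})
    sirnas = pd.DataFrame(sirna_rows)
    sirnas["efficient"] = rng.random(len(sirnas)) < cfg.per_sirna_efficacy

    # Placement: the library is spread evenly over all plates (each plate
    # carries ~n_sirnas/n_plates siRNAs in row-major sample wells, leaving
    # trailing sample positions unused), optionally shuffled to exercise
    # layout independence downstream.
    base, rem = divmod(n_sirnas, cfg.n_plates)
    slots = []
    for plate in range(1, cfg.n_plates + 1):
        n_here = base + (1 if plate <= rem else 0)
        slots.extend((plate, well) for well in sample_wells[:n_here])
    order = rng.permutation(len(slots)) if cfg.shuffle_placement else np.arange(len(slots))
    placements = [slots[order[i]] for i in range(n_sirnas)]
    lib = sirnas[["sirna", "gene"]].copy()
    lib["plate"] = [p for p, _ in placements]
    lib["well"] = [w for _, w in placements]
    library = SiRNALibrary(entries=lib, sirnas_per_gene=cfg.sirnas_per_gene)
    truth = TruthTable(genes=gene_classes, sirnas=sirnas)

    # Per-siRNA multiplicative gene effects on each channel.
    class_of = dict(zip(gene_classes["gene"], gene_classes["class"]))
    eff_e = np.ones(n_sirnas)
    eff_m = np.ones(n_sirnas)
    for i, (gene, efficient) in enumerate(zip(sirnas["gene"], sirnas["efficient"])):
        if not efficient:
            continue
        cls = class_of[gene]
        if cls == CLASS_EROD_HIT:
            eff_e[i] = cfg.erod_effect
        elif cls == CLASS_VIABILITY:
            eff_e[i] = cfg.viability_effect
            eff_m[i] = cfg.viability_effect

    # Assemble per-well rows: samples with content + controls, every plate.
    well_rows = []
    sirna_plate = lib["plate"].to_numpy()
    sirna_well = lib["well"].to_numpy()
    for i in range(n_sirnas):
        well_rows.append((sirna_plate[i], sirna_well[i], eff_e[i], eff_m[i]))
    for plate in range(1, cfg.n_plates + 1):
        for w in cfg.neg_wells:
            well_rows.append((plate, w, 1.0, 1.0))
        for w in cfg.pos_wells:
            well_rows.append((plate, w, cfg.pos_control_effect, 1.0))
    wr = pd.DataFrame(well_rows, columns=["plate", "well", "eff_e", "eff_m"])
    wr = wr.sort_values(["plate", "well"]).reset_index(drop=True)

    edge = np.ones(len(wr))
    if cfg.edge_effect is not None:
        from .screen_model import parse_well
        for j, w in enumerate(wr["well"]):
            r, c = parse_well(w, cfg.n_rows, cfg.n_cols)
            if r in (0, cfg.n_rows - 1) or c in (0, cfg.n_cols - 1):
                edge[j] = cfg.edge_effect

    frames = []
    traces: dict[tuple[int, int, str], np.ndarray] = {}
    times = np.linspace(0.0, cfg.kinetic_duration_min, cfg.kinetic_n_points)
    for rep in range(1, cfg.n_replicates + 1):
        plate_factor = np.exp(rng.normal(0.0, cfg.plate_effect_sd, cfg.n_plates))
        pf = plate_factor[wr["plate"].to_numpy() - 1]
        noise_e = np.exp(rng.normal(0.0, cfg.noise_sd, len(wr)))
        noise_m = np.exp(rng.normal(0.0, cfg.noise_sd, len(wr)))
        erod = cfg.base_erod * pf * edge * wr["eff_e"].to_numpy() * noise_e
        mb = cfg.base_mb * pf * edge * wr["eff_m"].to_numpy() * noise_m
        if cfg.kinetic:
            for j in range(len(wr)):
                key = (rep, int(wr.loc[j, "plate"]), str(wr.loc[j, "well"]))
                traces[key] = np.column_stack(
                    [times, cfg.kinetic_baseline + erod[j] * times]
                )
            frames.append(pd.DataFrame({
                "replicate": rep, "plate": wr["plate"], "well": wr["well"],
                "channel": "MB", "value": mb,
            }))
        else:
            frames.append(pd.DataFrame({
                "replicate": rep, "plate": wr["plate"], "well": wr["well"],
                "channel": "EROD", "value": erod,
            }))
            frames.append(pd.DataFrame({
                "replicate": rep, "plate": wr["plate"], "well": wr["well"],
                "channel": "MB", "value": mb,
            }))
    values = pd.concat(frames, ignore_index=True)
    screen = ScreenDataset(values=values, traces=traces)
    return screen, layout, library, truth


def evaluate_recovery(hit_table, truth: TruthTable) -> dict:
    """Sensitivity / specificity / hit-list FDR against the planted truth.

    sensitivity = called planted pathway genes / planted pathway genes;
    FDR = non-planted calls / all calls (0 when the hit list is empty);
    specificity = true negatives / all non-planted genes.
    """
    planted = set(truth.genes_of_class(CLASS_EROD_HIT))
    called = set(hit_table.hit_genes)
    all_genes = set(truth.genes["gene"])
    tp = len(called & planted)
    fp = len(called - planted)
    negatives = all_genes - planted
    sensitivity = tp / len(planted) if planted else float("nan")
    fdr = fp / len(called) if called else 0.0
    specificity = (
        len(negatives - called) / len(negatives) if negatives else float("nan")
    )
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "fdr": fdr,
        "n_called": len(called),
        "n_planted": len(planted),
        "n_true_positive": tp,
        "viability_genes_called": sorted(
            called & set(truth.genes_of_class(CLASS_VIABILITY))
        ),
    }
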