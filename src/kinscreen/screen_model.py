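"""Domain types, validation and delimited-text I/O for arrayed RNAi screens.

The screen modelled here is a dual-channel 96-well-plate assay: each well
carries one siRNA, and two readouts are taken per well — a kinetic
fluorescence channel (``EROD``, reporting CYP1A1 enzyme activity as a slope
in fluorescence units per minute) and a colorimetric cell-density channel
(``MB``, methylene-blue absorbance).  A library of r siRNAs per gene is
distributed over a stack of plates; every plate additionally carries fixed
negative-control wells (non-targeting siRNA / transfection reagent only) and
positive-control wells (siRNA that abolishes the pathway readout without
affecting cell density).

All tables travel as delimited text (TSV/CSV); annotation gene sets use the
GMT format; run configuration uses YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScreenError",
    "FormatError",
    "ValidationError",
    "NormalizationError",
    "DegenerateTraceError",
    "DegenerateDispersionError",
    "UndefinedCorrelationError",
    "PipelineError",
    "ROLE_SAMPLE",
    "ROLE_NEG",
    "ROLE_POS",
    "ROLE_EMPTY",
    "CHANNELS",
    "well_name",
    "parse_well",
    "PlateLayout",
    "SiRNALibrary",
    "ScreenDataset",
    "ScreenConfig",
    "AnnotationSet",
    "ValidationReport",
    "read_layout",
    "write_layout",
    "read_library",
    "write_library",
    "read_readouts",
    "write_readouts",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "validate_screen",
    "load_reported_hit_genes",
    "load_synthetic_go_annotation",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ScreenError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ScreenError):
    """A file does not conform to the expected delimited-text layout."""


class ValidationError(ScreenError):
    """Input data violates a structural invariant (bad well, negative value...)."""


class NormalizationError(ScreenError):
    """A plate cannot be normalized (missing controls, non-positive center)."""


class DegenerateTraceError(ScreenError):
    """A kinetic trace has too few distinct time points for a slope."""


class DegenerateDispersionError(ScreenError):
    """A score distribution has zero spread, so z-scores are undefined."""


class UndefinedCorrelationError(ScreenError):
    """Replicate correlation is undefined (zero variance in a replicate)."""


class PipelineError(ScreenError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# Well addressing
# ---------------------------------------------------------------------------

ROLE_SAMPLE = "sample"
ROLE_NEG = "neg_control"
ROLE_POS = "pos_control"
ROLE_EMPTY = "empty"
ROLES = (ROLE_SAMPLE, ROLE_NEG, ROLE_POS, ROLE_EMPTY)

CHANNELS = ("EROD", "MB")

_ROW_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

DEFAULT_NEG_WELLS = ("A12", "B12", "G12", "H12")
DEFAULT_POS_WELLS = ("G1", "H1")


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> address like ``"A12"`` (no leading zeros)."""
    return f"{_ROW_LETTERS[row]}{col + 1}"


def parse_well(address: str, n_rows: int = 8, n_cols: int = 12) -> tuple[int, int]:
    """Address like ``"A12"`` -> 0-based (row, col); raises ValidationError."""
    addr = str(address).strip()
    if len(addr) < 2 or addr[0].upper() not in _ROW_LETTERS:
        raise ValidationError(f"malformed well address {address!r}")
    row = _ROW_LETTERS.index(addr[0].upper())
    try:
        col = int(addr[1:]) - 1
    except ValueError:
        raise ValidationError(f"malformed well address {address!r}") from None
    if addr[1] == "0":
        raise ValidationError(f"well address {address!r} has a leading zero")
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise ValidationError(
            f"well {address!r} outside plate bounds {n_rows}x{n_cols}"
        )
    return row, col


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateLayout:
    """Geometry and role of every well on a plate.

    ``role_map`` is the per-plate role template shared by all plates of the
    screen: control wells sit at fixed addresses on every plate, all other
    wells are ``sample`` positions (a sample position without a library
    entry on a given plate is simply unused there).  An optional
    ``content_map`` may pin siRNA identifiers to wells for single-plate use;
    for multi-plate screens content comes from the :class:`SiRNALibrary`.
    """

    n_rows: int = 8
    n_cols: int = 12
    role_map: Mapping[str, str] = field(default_factory=dict)
    content_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_rows > len(_ROW_LETTERS):
            raise ValidationError("plate geometry out of range")
        seen: set[tuple[int, int]] = set()
        for addr, role in self.role_map.items():
            rc = parse_well(addr, self.n_rows, self.n_cols)
            if rc in seen:
                raise ValidationError(f"duplicate well address {addr!r} in layout")
            seen.add(rc)
            if role not in ROLES:
                raise ValidationError(f"unknown role {role!r} for well {addr!r}")
        for addr, sirna in self.content_map.items():
            parse_well(addr, self.n_rows, self.n_cols)
            if self.role_map.get(addr, ROLE_SAMPLE) != ROLE_SAMPLE:
                raise ValidationError(
                    f"content assigned to non-sample well {addr!r} ({sirna})"
                )

    @classmethod
    def default(
        cls,
        n_rows: int = 8,
        n_cols: int = 12,
        neg_wells: Sequence[str] = DEFAULT_NEG_WELLS,
        pos_wells: Sequence[str] = DEFAULT_POS_WELLS,
    ) -> "PlateLayout":
        """96-well layout with the conventional fixed control placement.

        Negative controls at A12/B12/G12/H12, positive controls at G1/H1;
        every other well is a sample position.
        """
        roles: dict[str, str] = {}
        for r in range(n_rows):
            for c in range(n_cols):
                roles[well_name(r, c)] = ROLE_SAMPLE
        for w in neg_wells:
            roles[w] = ROLE_NEG
        for w in pos_wells:
            roles[w] = ROLE_POS
        return cls(n_rows=n_rows, n_cols=n_cols, role_map=roles)

    # -- queries ----------------------------------------------------------

    def wells(self) -> list[str]:
        return [well_name(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def role(self, address: str) -> str:
        return self.role_map.get(address, ROLE_EMPTY)

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w in self.wells() if self.role(w) == role]

    @property
    def sample_wells(self) -> list[str]:
        return self.wells_with_role(ROLE_SAMPLE)

    @property
    def neg_control_wells(self) -> list[str]:
        return self.wells_with_role(ROLE_NEG)

    @property
    def pos_control_wells(self) -> list[str]:
        return self.wells_with_role(ROLE_POS)


# ---------------------------------------------------------------------------
# siRNA library
# ---------------------------------------------------------------------------

@dataclass
class SiRNALibrary:
    """Maps each siRNA to its target gene and its (plate, well) placement.

    ``entries`` columns: ``sirna``, ``gene``, ``plate`` (1-based int),
    ``well``, and optionally ``sequence``.  Placement uniqueness and siRNA-id
    uniqueness are always enforced; the r-siRNAs-per-gene design rule is
    checked by :meth:`validate` / :func:`validate_screen` so that deliberately
    incomplete libraries can still be constructed and reported on.
    """

    entries: pd.DataFrame
    sirnas_per_gene: int = 3

    def __post_init__(self) -> None:
        required = {"sirna", "gene", "plate", "well"}
        missing = required - set(self.entries.columns)
        if missing:
            raise FormatError(f"library table missing columns: {sorted(missing)}")
        df = self.entries.reset_index(drop=True).copy()
        df["plate"] = df["plate"].astype(int)
        df["sirna"] = df["sirna"].astype(str)
        df["gene"] = df["gene"].astype(str)
        df["well"] = df["well"].astype(str)
        if df["sirna"].duplicated().any():
            dup = df.loc[df["sirna"].duplicated(), "sirna"].iloc[0]
            raise ValidationError(f"duplicate siRNA identifier {dup!r}")
        if df.duplicated(subset=["plate", "well"]).any():
            bad = df[df.duplicated(subset=["plate", "well"])].iloc[0]
            raise ValidationError(
                f"plate {bad['plate']} well {bad['well']} occupied by more than one siRNA"
            )
        self.entries = df

    def validate(self) -> None:
        """Raise unless every gene has exactly ``sirnas_per_gene`` entries."""
        bad = self.genes_with_wrong_multiplicity()
        if bad:
            raise ValidationError(
                f"{len(bad)} gene(s) do not have exactly "
                f"{self.sirnas_per_gene} siRNAs, e.g. {sorted(bad)[:5]}"
            )

    def genes_with_wrong_multiplicity(self) -> dict[str, int]:
        counts = self.entries.groupby("gene")["sirna"].count()
        wrong = counts[counts != self.sirnas_per_gene]
        return dict(wrong)

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries["gene"].unique())

    @property
    def sirnas(self) -> list[str]:
        return list(self.entries["sirna"])

    def gene_of(self, sirna: str) -> str:
        sub = self.entries.loc[self.entries["sirna"] == sirna, "gene"]
        if sub.empty:
            raise ValidationError(f"unknown siRNA {sirna!r}")
        return sub.iloc[0]

    def plate_contents(self, plate: int) -> dict[str, str]:
        """well -> siRNA for one plate."""
        sub = self.entries[self.entries["plate"] == plate]
        return dict(zip(sub["well"], sub["sirna"]))


# ---------------------------------------------------------------------------
# Screen dataset
# ---------------------------------------------------------------------------

@dataclass
class ScreenDataset:
    """Per-well raw readouts for both channels across replicates and plates.

    ``values`` is a long table with columns ``replicate`` (1-based),
    ``plate`` (1-based), ``well``, ``channel`` (``EROD``/``MB``) and
    ``value`` (non-negative).  Missing wells are absent rows, never imputed.
    ``traces`` optionally holds kinetic fluorescence traces keyed by
    (replicate, plate, well) as (n, 2) arrays of (time_min, fluorescence);
    where a trace exists it takes precedence over any precomputed EROD value.
    """

    values: pd.DataFrame
    traces: dict[tuple[int, int, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"replicate", "plate", "well", "channel", "value"}
        missing = required - set(self.values.columns)
        if missing:
            raise FormatError(f"readout table missing columns: {sorted(missing)}")
        df = self.values.reset_index(drop=True).copy()
        df["replicate"] = df["replicate"].astype(int)
        df["plate"] = df["plate"].astype(int)
        df["well"] = df["well"].astype(str)
        df["channel"] = df["channel"].astype(str)
        df["value"] = df["value"].astype(float)
        bad_channel = ~df["channel"].isin(CHANNELS)
        if bad_channel.any():
            raise ValidationError(
                f"unknown channel {df.loc[bad_channel, 'channel'].iloc[0]!r}"
            )
        neg = df["value"] < 0
        if neg.any():
            row = df[neg].iloc[0]
            raise ValidationError(
                "negative readout at (replicate, plate, well) = "
                f"({row['replicate']}, {row['plate']}, {row['well']})"
            )
        if df.duplicated(subset=["replicate", "plate", "well", "channel"]).any():
            row = df[df.duplicated(subset=["replicate", "plate", "well", "channel"])].iloc[0]
            raise ValidationError(
                "duplicate readout for (replicate, plate, well, channel) = "
                f"({row['replicate']}, {row['plate']}, {row['well']}, {row['channel']})"
            )
        self.values = df

    @property
    def n_replicates(self) -> int:
        return int(self.values["replicate"].nunique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.values["replicate"].unique())

    @property
    def plates(self) -> list[int]:
        return sorted(self.values["plate"].unique())

    def get(self, replicate: int, plate: int, well: str, channel: str) -> float:
        df = self.values
        m = (
            (df["replicate"] == replicate)
            & (df["plate"] == plate)
            & (df["well"] == well)
            & (df["channel"] == channel)
        )
        sub = df.loc[m, "value"]
        if sub.empty:
            raise KeyError((replicate, plate, well, channel))
        return float(sub.iloc[0])

    def wide(self) -> pd.DataFrame:
        """One row per (replicate, plate, well) with ``EROD``/``MB`` columns."""
        w = self.values.pivot_table(
            index=["replicate", "plate", "well"],
            columns="channel",
            values="value",
            aggfunc="first",
        ).reset_index()
        w.columns.name = None
        for ch in CHANNELS:
            if ch not in w.columns:
                w[ch] = np.nan
        return w


# ---------------------------------------------------------------------------
# Screen configuration
# ---------------------------------------------------------------------------

@dataclass
class ScreenConfig:
    """Analysis parameters for the full pipeline.

    top_k
        Number of top-ranked siRNAs from which gene hits are drawn (150).
    min_concordant
        m of the >=m-of-r concordance rule (2): a gene is a hit only when at
        least m of its r siRNAs land in the top k, guarding against
        single-siRNA off-target effects.
    viability_z_threshold
        |z| cutoff on the cell-density channel above which a siRNA is
        considered a viability confound and removed from hit candidacy;
        ``inf`` reproduces ratio-only behaviour.
    normalization_method
        ``plate_median`` (default) or ``percent_of_neg_controls``.
    score_on_log_ratio
        Score log2 of the normalized EROD/MB ratio (default) or the raw ratio.
    direction
        ``reduction`` makes pathway-reducing siRNAs score positive.
    """

    top_k: int = 150
    min_concordant: int = 2
    sirnas_per_gene: int = 3
    viability_z_threshold: float = 2.0
    normalization_method: str = "plate_median"
    score_on_log_ratio: bool = True
    direction: str = "reduction"
    mad_consistency_constant: float = 1.4826
    mb_floor: float = 0.1
    viability_filter_before_ranking: bool = True
    min_term_size: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_concordant <= self.sirnas_per_gene):
            raise ValidationError("require 0 < min_concordant <= sirnas_per_gene")
        if self.top_k < self.min_concordant:
            raise ValidationError("require top_k >= min_concordant")
        if not self.viability_z_threshold > 0:
            raise ValidationError("viability_z_threshold must be positive")
        if self.normalization_method not in ("plate_median", "percent_of_neg_controls"):
            raise ValidationError(
                f"unknown normalization_method {self.normalization_method!r}"
            )
        if self.direction not in ("reduction", "increase"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if not self.mb_floor > 0:
            raise ValidationError("mb_floor must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Annotation sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Flat term -> gene-set annotation with an explicit background universe."""

    term_map: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        self.term_map = {t: set(g) for t, g in self.term_map.items()}
        if self.universe is None or len(self.universe) == 0:
            # Default background: union of all annotated genes.
            self.universe = set().union(*self.term_map.values()) if self.term_map else set()
        self.universe = set(self.universe)
        for term, genes in self.term_map.items():
            if not genes <= self.universe:
                raise ValidationError(
                    f"term {term!r} contains genes outside the universe"
                )

    @property
    def n_terms(self) -> int:
        return len(self.term_map)


def read_gmt(path, universe: Iterable[str] | None = None) -> AnnotationSet:
    """Parse a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are deduplicated.  The universe defaults to
    the union of all annotated genes unless supplied.
    """
    term_map: dict[str, set] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has fewer than 3 fields"
                )
            term = fields[0]
            genes = {g for g in fields[2:] if g}
            term_map[term] = genes
    return AnnotationSet(term_map=term_map, universe=set(universe) if universe else set())


def write_gmt(annotation: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation.term_map):
            genes = sorted(annotation.term_map[term])
            fh.write("\t".join([term, "na", *genes]) + "\n")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    """Read a CSV or TSV, inferring the delimiter from the header line."""
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") else ","
    try:
        return pd.read_csv(
            path, sep=sep, dtype={"well": str}, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_layout(path) -> PlateLayout:
    """Layout TSV/CSV with columns ``well``, ``role`` (optionally ``sirna``)."""
    df = _read_delimited(path)
    if not {"well", "role"} <= set(df.columns):
        raise FormatError("layout file requires columns 'well' and 'role'")
    role_map = dict(zip(df["well"].astype(str), df["role"].astype(str)))
    content: dict[str, str] = {}
    if "sirna" in df.columns:
        for w, s in zip(df["well"].astype(str), df["sirna"]):
            if isinstance(s, str) and s:
                content[w] = s
    n_rows = max(parse_well(w, 26, 10_000)[0] for w in role_map) + 1
    n_cols = max(parse_well(w, 26, 10_000)[1] for w in role_map) + 1
    return PlateLayout(
        n_rows=max(n_rows, 1), n_cols=max(n_cols, 1),
        role_map=role_map, content_map=content,
    )


def write_layout(layout: PlateLayout, path) -> None:
    rows = [{"well": w, "role": layout.role(w)} for w in layout.wells()]
    df = pd.DataFrame(rows)
    if layout.content_map:
        df["sirna"] = df["well"].map(layout.content_map)
    df.to_csv(path, sep="\t", index=False)


def read_library(path, sirnas_per_gene: int = 3) -> SiRNALibrary:
    df = _read_delimited(path)
    required = {"sirna", "gene", "plate", "well"}
    if not required <= set(df.columns):
        raise FormatError(
            f"library file requires columns {sorted(required)}"
        )
    return SiRNALibrary(entries=df, sirnas_per_gene=sirnas_per_gene)


def write_library(library: SiRNALibrary, path) -> None:
    library.entries.to_csv(path, sep="\t", index=False)


_READOUT_COLUMNS = ["experiment", "plate", "well", "channel", "value"]
_KINETIC_COLUMNS = ["time", "fluorescence"]


def read_readouts(
    path,
    layout: PlateLayout | None = None,
    library: SiRNALibrary | None = None,
) -> ScreenDataset:
    """Read per-well readouts, grouping kinetic rows into traces.

    Expected columns: ``experiment, plate, well, channel, value`` for
    precomputed activities; kinetic rows instead carry ``time`` (minutes)
    and ``fluorescence`` with ``value`` empty.  Wells are checked against
    the layout when one is given.
    """
    df = _read_delimited(path)
    missing = set(_READOUT_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise FormatError(f"readout file missing columns: {sorted(missing)}")
    has_kinetic = set(_KINETIC_COLUMNS) <= set(df.columns)
    if "value" not in df.columns and not has_kinetic:
        raise FormatError("readout file missing columns: ['value']")
    if "value" not in df.columns:
        df["value"] = np.nan

    df["experiment"] = df["experiment"].astype(int)
    df["plate"] = df["plate"].astype(int)
    df["well"] = df["well"].astype(str)
    df["channel"] = df["channel"].astype(str)

    if layout is not None:
        known = set(layout.wells())
        bad = ~df["well"].isin(known)
        if bad.any():
            raise ValidationError(
                f"well {df.loc[bad, 'well'].iloc[0]!r} not present in layout"
            )

    traces: dict[tuple[int, int, str], np.ndarray] = {}
    if has_kinetic:
        kin = df[df["time"].notna() & df["fluorescence"].notna()]
        for (exp, plate, well), grp in kin.groupby(["experiment", "plate", "well"]):
            arr = (
                grp[["time", "fluorescence"]]
                .astype(float)
                .sort_values("time")
                .to_numpy()
            )
            if (arr[:, 1] < 0).any():
                raise ValidationError(
                    "negative fluorescence at (replicate, plate, well) = "
                    f"({exp}, {plate}, {well})"
                )
            traces[(int(exp), int(plate), str(well))] = arr
        df = df.drop(index=kin.index)

    df = df[df["value"].notna()]
    values = df.rename(columns={"experiment": "replicate"})[
        ["replicate", "plate", "well", "channel", "value"]
    ]
    return ScreenDataset(values=values.reset_index(drop=True), traces=traces)


def write_readouts(screen: ScreenDataset, path) -> None:
    """Write a ScreenDataset back to delimited text (lossless round trip)."""
    df = screen.values.rename(columns={"replicate": "experiment"})
    df = df[["experiment", "plate", "well", "channel", "value"]].copy()
    if screen.traces:
        df["time"] = np.nan
        df["fluorescence"] = np.nan
        kin_rows = []
        for (rep, plate, well), arr in sorted(screen.traces.items()):
            for t, f in arr:
                kin_rows.append(
                    {
                        "experiment": rep,
                        "plate": plate,
                        "well": well,
                        "channel": "EROD",
                        "value": np.nan,
                        "time": t,
                        "fluorescence": f,
                    }
                )
        df = pd.concat([df, pd.DataFrame(kin_rows)], ignore_index=True)
    # %.17g guarantees a bit-exact float round trip through text
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only completeness check of a screen against layout + library.

    ``missing_wells`` lists (replicate, plate, well, channel) triples that the
    library says should carry a measurement but do not; ``orphan_sirnas`` are
    library entries never measured in any replicate; ``gene_multiplicity``
    maps genes to their (wrong) siRNA count when it differs from the design r.
    """

    missing_wells: list[tuple[int, int, str, str]] = field(default_factory=list)
    orphan_sirnas: list[str] = field(default_factory=list)
    gene_multiplicity: dict[str, int] = field(default_factory=dict)
    unknown_wells: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.missing_wells
            or self.orphan_sirnas
            or self.gene_multiplicity
            or self.unknown_wells
        )

    def summary(self) -> dict:
        return {
            "ok": self.ok,
            "n_missing_wells": len(self.missing_wells),
            "n_orphan_sirnas": len(self.orphan_sirnas),
            "n_genes_wrong_multiplicity": len(self.gene_multiplicity),
            "n_unknown_wells": len(self.unknown_wells),
        }


def validate_screen(
    screen: ScreenDataset,
    layout: PlateLayout,
    library: SiRNALibrary,
) -> ValidationReport:
    """Check completeness of a screen; empty report iff the screen is complete."""
    report = ValidationReport()
    report.gene_multiplicity = library.genes_with_wrong_multiplicity()

    measured = set(
        zip(
            screen.values["replicate"],
            screen.values["plate"],
            screen.values["well"],
            screen.values["channel"],
        )
    )
    for key in screen.traces:
        measured.add((*key, "EROD"))
    replicates = screen.replicates

    measured_pw = {(p, w) for (_, p, w, _) in measured}
    lib = library.entries
    for sirna, plate, well in zip(lib["sirna"], lib["plate"], lib["well"]):
        if (plate, well) not in measured_pw:
            report.orphan_sirnas.append(sirna)
            continue
        for rep in replicates:
            for ch in CHANNELS:
                if (rep, plate, well, ch) not in measured:
                    report.missing_wells.append((rep, plate, well, ch))

    known_wells = set(layout.wells())
    for rep, plate, well, _ in sorted(measured):
        if well not in known_wells and (rep, plate, well) not in report.unknown_wells:
            report.unknown_wells.append((rep, plate, well))
    return report


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("kinscreen.data").joinpath(name).read_text()


def load_reported_hit_genes() -> list[str]:
    """The 22 kinases called as EROD-reducing hits by the original kinome-wide
    RNAi screen (>=2-of-3 siRNA concordance within the top 150 z-scores)."""
    return [
        line.strip()
        for line in _data_text("kinome_hits.txt").splitlines()
        if line.strip() and not line.startswith("#")
    ]


def load_synthetic_go_annotation() -> AnnotationSet:
    """Synthetic GO-style molecular-function annotation for the packaged hit
    list.

    Term memberships for the packaged hit genes reproduce the curated
    hit-per-term counts and term sizes of the original screen's enrichment
    analysis; all other members are synthetic padding symbols (``PADnnn``)
    because the original annotation source is not publicly retrievable.
    Suitable for exercising the enrichment machinery, not for biology.
    """
    buf = _data_text("go_terms_synthetic.gmt")
    term_map: dict[str, set] = {}
    for line in buf.splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        term_map[fields[0]] = {g for g in fields[2:] if g}
    return AnnotationSet(term_map=term_map, universe=set())
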