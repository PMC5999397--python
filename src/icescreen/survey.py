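"""Survey data model and aggregate statistics over 46 grid preparations.

The package ships a transcription of the screening survey's two summary
tables as a CSV fixture: per sample, the grid type and preparation family,
ice thickness at hole centre / ~100 nm from the hole edge / over the
substrate, particle layer counts, apparent preferred orientation, the
minimum particle-layer distance from the air-water interface, interface
taxonomy codes, and particle-layer tilt entries per region.

Aggregation follows the survey's conventions: thickness statistics use
the minimum of a printed range, tilt entries use range midpoints, the
standard deviation is the population SD by default, and every statistic
carries a propagated measurement error

    dq = sqrt(sum(dx_i^2)) / N

(5 nm per thickness measurement, 1 degree per tilt) combined with the SD
in quadrature.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "GroupStat",
    "SurveySchemaError",
    "load_survey",
    "default_fixture_path",
    "propagate_measurement_error",
    "group_ice_stats",
    "group_layer_fractions",
    "group_tilt_stats",
    "classify_conditions",
]

GRID_FAMILIES = (
    "gold_spotiton",
    "carbon_spotiton",
    "carbon_conventional",
    "gold_conventional",
)

LOCATIONS = ("center", "edge", "substrate")

THICKNESS_ERROR_NM = 5.0
TILT_ERROR_DEG = 1.0

#: layer tokens that admit a single non-overlapping particle layer
_SINGLE_CAPABLE = {"1", "1-2", "0-1", "0-2"}
_MISSING = {"", "--", "nan"}


class SurveySchemaError(ValueError):
    """Fixture violation; names the offending row and column."""


@dataclass
class SampleRecord:
    """One survey sample (one grid preparation)."""

    sample_id: int
    name: str
    grid_type: str | None
    grid_family: str | None
    concentration_mg_ml: float | None
    intentionally_thick: bool
    affinity_overlay: bool
    no_interface_interaction: bool
    thickness: dict  # location -> (min, max) nm or None
    layers: dict  # location -> token or None
    preferred_orientation: str  # yes | some | no | unknown
    min_layer_distance: str | None  # "<5" | "5" | "5-10" | "10"
    ice_bottom: str | None
    ice_top: str | None
    region_codes: dict  # (side, location) -> code string or None
    tilts: dict  # location -> list of (lo, hi) degree ranges

    def thickness_min(self, location: str) -> float | None:
        rng = self.thickness.get(location)
        return None if rng is None else rng[0]


def _parse_range(tok: str, row: int, col: str) -> tuple[float, float] | None:
    tok = tok.strip()
    if tok in _MISSING:
        return None
    m = re.fullmatch(r"(-?\d+(?:\.\d+)?)(?:-(\d+(?:\.\d+)?))?", tok)
    if not m:
        raise SurveySchemaError(f"row {row}, column {col!r}: cannot parse {tok!r}")
    lo = float(m.group(1))
    hi = float(m.group(2)) if m.group(2) else lo
    if hi < lo:
        raise SurveySchemaError(
            f"row {row}, column {col!r}: malformed range {tok!r} (min > max)"
        )
    return lo, hi


def _parse_tilts(tok: str, row: int, col: str) -> list[tuple[float, float]]:
    tok = (tok or "").strip()
    if tok in _MISSING:
        return []
    return [r for t in tok.split(";") if (r := _parse_range(t, row, col)) is not None]


def _grid_family(grid_type: str | None) -> str | None:
    """Documented predicate over grid-type strings.

    Spotiton preparations split on gold vs carbon substrate; everything
    else is conventional plunging, carbon unless the type is gold-only.
    """
    if not grid_type:
        return None
    g = grid_type.lower()
    if "spotiton" in g:
        return "gold_spotiton" if "gold" in g else "carbon_spotiton"
    if "carbon" in g:
        return "carbon_conventional"
    if "gold" in g:
        return "gold_conventional"
    return None


def default_fixture_path() -> str:
    return str(resources.files("icescreen.data") / "survey_table.csv")


def load_survey(path: str | None = None) -> list[SampleRecord]:
    """Load the survey fixture (or a user CSV with the same schema)."""
    path = path or default_fixture_path()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {
        "sample_id", "name", "grid_type", "intentionally_thick",
        "affinity_overlay", "no_interface_interaction",
        "t_center", "t_edge", "t_substrate",
        "layers_center", "layers_edge", "layers_substrate",
        "preferred_orientation", "min_layer_distance",
        "ice_bottom", "ice_top", "tilts_center", "tilts_edge",
    }
    missing = required - set(df.columns)
    if missing:
        raise SurveySchemaError(f"fixture missing columns: {sorted(missing)}")
    records: list[SampleRecord] = []
    for _, row in df.iterrows():
        sid = int(row["sample_id"])
        grid_type = None if row["grid_type"] in _MISSING else row["grid_type"]
        name = row["name"]
        conc = None
        m = re.search(r"\(([\d.]+)\s*mg/mL\)", name)
        if m:
            conc = float(m.group(1))
        ori = row["preferred_orientation"].strip().lower()
        if ori not in ("yes", "some", "no", "unknown"):
            raise SurveySchemaError(
                f"row {sid}, column 'preferred_orientation': bad token {ori!r}"
            )
        thickness = {
            loc: _parse_range(row[f"t_{loc}"], sid, f"t_{loc}") for loc in LOCATIONS
        }
        layers = {
            loc: (None if row[f"layers_{loc}"] in _MISSING else row[f"layers_{loc}"])
            for loc in LOCATIONS
        }
        codes = {}
        for side in ("bottom", "top"):
            for loc in ("center", "edge"):
                col = f"codes_{side}_{loc}"
                val = row.get(col, "--")
                codes[(side, loc)] = None if val in _MISSING else val
        records.append(
            SampleRecord(
                sample_id=sid,
                name=name,
                grid_type=grid_type,
                grid_family=_grid_family(grid_type),
                concentration_mg_ml=conc,
                intentionally_thick=row["intentionally_thick"].strip() == "1",
                affinity_overlay=row["affinity_overlay"].strip() == "1",
                no_interface_interaction=row["no_interface_interaction"].strip() == "1",
                thickness=thickness,
                layers=layers,
                preferred_orientation=ori,
                min_layer_distance=(
                    None if row["min_layer_distance"] in _MISSING
                    else row["min_layer_distance"]
                ),
                ice_bottom=None if row["ice_bottom"] in _MISSING else row["ice_bottom"],
                ice_top=None if row["ice_top"] in _MISSING else row["ice_top"],
                region_codes=codes,
                tilts={
                    "center": _parse_tilts(row["tilts_center"], sid, "tilts_center"),
                    "edge": _parse_tilts(row["tilts_edge"], sid, "tilts_edge"),
                },
            )
        )
    return records


@dataclass
class GroupStat:
    """Aggregate of one quantity over a sample group."""

    n: int
    mean: float
    sd: float
    meas_error_each: float
    propagated_error: float
    combined: float = field(init=False)
    values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group must contain at least one value")
        if min(self.sd, self.propagated_error) < 0:
            raise ValueError("dispersion terms must be >= 0")
        self.combined = math.sqrt(self.sd**2 + self.propagated_error**2)


def propagate_measurement_error(errors: list[float]) -> float:
    """dq = sqrt(sum(dx^2)) / N for independent per-measurement errors dx."""
    if len(errors) == 0:
        raise ValueError("need at least one measurement error")
    e = np.asarray(errors, dtype=float)
    if (e < 0).any():
        raise ValueError("measurement errors must be >= 0")
    return float(np.sqrt(np.sum(e**2)) / len(e))


def _group_stat(values: list[float], err_each: float, ddof: int) -> GroupStat:
    v = np.asarray(values, dtype=float)
    sd = float(v.std(ddof=ddof)) if len(v) > ddof else 0.0
    return GroupStat(
        n=len(v),
        mean=float(v.mean()),
        sd=sd,
        meas_error_each=err_each,
        propagated_error=propagate_measurement_error([err_each] * len(v)),
        values=list(map(float, v)),
    )


def group_ice_stats(
    records: list[SampleRecord],
    family: str,
    location: str = "center",
    range_rule: str = "min",
    exclude_intentionally_thick: bool = False,
    ddof: int = 0,
) -> GroupStat:
    """Thickness statistics (nm) for one preparation family and location.

    The minimum of a printed range enters by default, the population SD
    convention applies unless ``ddof=1``, and each value carries the 5 nm
    measurement error.
    """
    if family not in GRID_FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if location not in LOCATIONS:
        raise ValueError(f"unknown location {location!r}")
    vals = []
    for r in records:
        if r.grid_family != family:
            continue
        if exclude_intentionally_thick and r.intentionally_thick:
            continue
        rng = r.thickness.get(location)
        if rng is None:
            continue
        if range_rule == "min":
            vals.append(rng[0])
        elif range_rule == "midpoint":
            vals.append(0.5 * (rng[0] + rng[1]))
        else:
            raise ValueError(f"unknown range rule {range_rule!r}")
    if not vals:
        raise ValueError(f"no {location} thickness values for family {family!r}")
    return _group_stat(vals, THICKNESS_ERROR_NM, ddof)


def group_layer_fractions(
    records: list[SampleRecord], location: str = "center"
) -> dict:
    """Fractions of samples with single / double particle layers.

    Tokens ``1`` and ``1-2`` count toward single, ``2`` and ``1-2`` toward
    double (a sample whose holes vary counts in both); the denominator is
    every sample with a countable token at the location.
    """
    single = double = total = 0
    for r in records:
        tok = r.layers.get(location)
        if tok is None or tok == "uniform":
            continue
        total += 1
        if tok in ("1", "1-2"):
            single += 1
        if tok in ("2", "1-2"):
            double += 1
    return {
        "n_single": single,
        "n_double": double,
        "n_total": total,
        "single_percent": 100.0 * single / total if total else float("nan"),
        "double_percent": 100.0 * double / total if total else float("nan"),
    }


def group_tilt_stats(
    records: list[SampleRecord], location: str = "center", ddof: int = 0
) -> GroupStat:
    """Particle-layer tilt statistics (degrees) over every region entry.

    Every tilt entry in the tables contributes (both interfaces, plus all
    'or' alternatives); range entries contribute their midpoint; each
    entry carries the 1 degree measurement error.
    """
    vals = []
    for r in records:
        for lo, hi in r.tilts.get(location, []):
            vals.append(0.5 * (lo + hi))
    if not vals:
        raise ValueError(f"no tilt entries at {location!r}")
    return _group_stat(vals, TILT_ERROR_DEG, ddof)


def classify_conditions(record: SampleRecord, location: str = "center") -> str:
    """Classify a sample as ``ideal`` / ``near_ideal`` / ``neither``.

    Near-ideal regions have < 100 nm ice, a layer token admitting a single
    non-overlapping particle layer, and little or no preferred orientation;
    ideal adds evidence of no particle-interface interaction.  Missing
    fields give ``indeterminate`` rather than a guess.
    """
    t = record.thickness_min(location)
    tok = record.layers.get(location)
    ori = record.preferred_orientation
    if t is None or tok is None or tok == "uniform" or ori == "unknown":
        return "indeterminate"
    near = t < 100.0 and tok in _SINGLE_CAPABLE and ori in ("no", "some")
    if near and record.no_interface_interaction:
        return "ideal"
    return "near_ideal" if near else "neither"
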