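"""Internal-standard-normalized quantification and surrogate semiquantification.

Feature areas become concentrations through calibration curves fitted on
internal-standard-normalized responses. The retention-time axis is
partitioned into internal-standard windows (the deuterated/13C standard
eluting nearest to the analyte corrects its instrumental drift).
Tentatively identified chemicals without their own standard are
semiquantified with the calibration curve of a structurally similar
standard; concentrations below the method detection limit are censored,
never silently reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, SchemaError

__all__ = [
    "InternalStandardMap",
    "CalibrationCurve",
    "QuantifiedChemical",
    "default_is_map",
    "assign_internal_standard",
    "normalize_area",
    "fit_calibration",
    "quantify",
    "mdl_from_blanks",
    "surrogate_semiquantify",
    "coelution_split",
    "read_calibration_csv",
]


@dataclass
class InternalStandardMap:
    """Half-open RT windows, each served by one internal standard."""

    windows: list[tuple[float, float, str]]

    def __post_init__(self):
        self.windows = sorted(self.windows)
        for (a0, a1, _), (b0, _, _) in zip(self.windows, self.windows[1:]):
            if a1 > b0:
                raise ConfigError("internal-standard windows overlap")
        for lo, hi, _ in self.windows:
            if hi <= lo:
                raise ConfigError("empty internal-standard window")


def default_is_map() -> InternalStandardMap:
    """The three-window GC map: acenaphthene-D10 below 12 min, PCB118-13C12
    between 12 and 19 min, benzo[a]pyrene-D12 above 19 min."""
    return InternalStandardMap(
        [
            (0.0, 12.0, "acenaphthene-D10"),
            (12.0, 19.0, "PCB118-13C12"),
            (19.0, math.inf, "benzo[a]pyrene-D12"),
        ]
    )


def assign_internal_standard(rt: float, is_map: InternalStandardMap) -> str:
    """Look up the internal standard for a retention time (lower-inclusive)."""
    for lo, hi, name in is_map.windows:
        if lo <= rt < hi:
            return name
    raise ConfigError(f"retention time {rt} min not covered by the IS map")


def normalize_area(analyte_area: float, is_area: float) -> float:
    """Internal-standard response ratio; cancels common instrumental drift."""
    if is_area <= 0:
        raise ConfigError("internal-standard area must be positive (sample failure)")
    if analyte_area < 0:
        raise ValueError("negative analyte area")
    return analyte_area / is_area


@dataclass
class CalibrationCurve:
    """OLS line through (concentration, IS-normalized area) levels.

    Concentrations are vial concentrations (ug/mL); ``mdl`` is on the same
    scale. Unusable curves (non-positive slope) never construct.
    """

    analyte: str
    is_name: str
    levels: list[tuple[float, float]]
    slope: float
    intercept: float
    r2: float
    mdl: float

    def __post_init__(self):
        if len(self.levels) < 3:
            raise ValueError("calibration needs at least 3 levels")
        if self.slope <= 0:
            raise ValueError(f"unusable calibration for {self.analyte}: slope <= 0")


def fit_calibration(
    levels: Sequence[tuple[float, float]],
    analyte: str = "",
    is_name: str = "",
    mdl: float | None = None,
    weighting: str | None = None,
) -> CalibrationCurve:
    """Fit the calibration line; unweighted OLS by default, ``"1/x"`` optional.

    Without an explicit (or blank-derived) MDL the lowest calibration level
    is used as a conservative fallback.
    """
    levels = [(float(c), float(a)) for c, a in levels]
    if len(levels) < 3:
        raise ValueError("calibration needs at least 3 levels")
    conc = np.array([c for c, _ in levels])
    area = np.array([a for _, a in levels])
    if weighting is None:
        res = stats.linregress(conc, area)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    elif weighting == "1/x":
        w = 1.0 / conc
        W = np.diag(w)
        Xd = np.column_stack([conc, np.ones_like(conc)])
        beta = np.linalg.solve(Xd.T @ W @ Xd, Xd.T @ W @ area)
        slope, intercept = float(beta[0]), float(beta[1])
        pred = Xd @ beta
        r2 = 1.0 - np.sum(w * (area - pred) ** 2) / np.sum(
            w * (area - np.average(area, weights=w)) ** 2
        )
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return CalibrationCurve(
        analyte=analyte,
        is_name=is_name,
        levels=levels,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        mdl=float(mdl) if mdl is not None else float(conc.min()),
    )


def mdl_from_blanks(blank_normalized_areas: Sequence[float], curve: CalibrationCurve) -> float:
    """Method detection limit: 3 x SD of blank responses through the curve."""
    blanks = np.asarray(blank_normalized_areas, dtype=float)
    if len(blanks) < 2:
        raise ValueError("need at least 2 blank measurements")
    return 3.0 * float(np.std(blanks, ddof=1)) / curve.slope


@dataclass
class QuantifiedChemical:
    """One chemical's concentration in one sample, with provenance.

    Censored records carry ``concentration=None`` and render as ``<MDL``
    (per-gram MDL attached); ``method`` distinguishes authentic calibration
    from surrogate semiquantification.
    """

    structure_id: str
    sample_id: str
    concentration: float | None  # ug/g_sed,dw
    method: str  # authentic | surrogate
    censored: bool = False
    mdl_per_g: float | None = None
    similarity_group: str | None = None
    surrogate_of: str | None = None
    coeluted_with: tuple[str, ...] = ()

    def __post_init__(self):
        if self.method not in {"authentic", "surrogate"}:
            raise ValueError(f"unknown quantification method {self.method!r}")
        if self.censored and self.mdl_per_g is None:
            raise ValueError("censored record needs an MDL")

    def display(self) -> str:
        if self.censored:
            return f"<{self.mdl_per_g:g}"
        return f"{self.concentration:g}"


def quantify(
    curve: CalibrationCurve,
    normalized_area: float,
    sample_mass: float,
    extract_volume: float,
    sample_id: str = "",
    structure_id: str | None = None,
    force_uncensored: bool = False,
) -> QuantifiedChemical:
    """Convert an IS-normalized area to a per-gram sediment concentration.

    vial concentration = (area - intercept)/slope (ug/mL); per-gram
    concentration = vial x extract_volume / sample_mass (ug/g_sed,dw).
    Vial concentrations below the curve's MDL are censored unless
    ``force_uncensored``.
    """
    if sample_mass <= 0 or extract_volume <= 0:
        raise ValueError("sample mass and extract volume must be positive")
    vial = (normalized_area - curve.intercept) / curve.slope
    factor = extract_volume / sample_mass
    mdl_per_g = curve.mdl * factor
    sid = structure_id or curve.analyte
    if vial < curve.mdl and not force_uncensored:
        return QuantifiedChemical(
            sid, sample_id, None, "authentic", censored=True, mdl_per_g=mdl_per_g
        )
    return QuantifiedChemical(
        sid, sample_id, vial * factor, "authentic", censored=False, mdl_per_g=mdl_per_g
    )


def surrogate_semiquantify(
    structure_id: str,
    similarity_group: str,
    normalized_area: float,
    group_curves: Mapping[str, Sequence[tuple[CalibrationCurve, float]]],
    feature_ri: float | None,
    sample_mass: float,
    extract_volume: float,
    sample_id: str = "",
) -> tuple[QuantifiedChemical | None, str | None]:
    """Semiquantify a tentatively identified chemical with a group surrogate.

    ``group_curves`` maps similarity group -> [(curve, standard RI), ...];
    the authentic standard with the RI closest to the feature's is chosen
    as the surrogate. Returns ``(record, None)`` on success or
    ``(None, reason)`` when the group has no standard.
    """
    curves = list(group_curves.get(similarity_group, ()))
    if not curves:
        return None, f"no authentic standard in similarity group {similarity_group!r}"
    if feature_ri is None:
        curve = curves[0][0]
    else:
        curve = min(curves, key=lambda cr: abs(cr[1] - feature_ri))[0]
    rec = quantify(
        curve, normalized_area, sample_mass, extract_volume, sample_id, structure_id
    )
    rec.method = "surrogate"
    rec.similarity_group = similarity_group
    rec.surrogate_of = curve.analyte
    return rec, None


def coelution_split(
    total_concentration: float, coeluters: Sequence[str]
) -> dict[str, float]:
    """Split a coeluting peak's concentration equally among its structures.

    Chromatographically unresolved isomers cannot be apportioned from the
    shared peak, so equal concentrations are assumed; each share carries
    the full coeluter list as provenance.
    """
    if not coeluters:
        raise ValueError("need at least one coeluting structure")
    if total_concentration < 0:
        raise ValueError("negative concentration")
    share = total_concentration / len(coeluters)
    return {s: share for s in coeluters}


def read_calibration_csv(path) -> dict[str, CalibrationCurve]:
    """Read calibration series (analyte, is_name, level_conc, analyte_area,
    is_area) and fit one curve per analyte."""
    df = pd.read_csv(path)
    required = {"analyte", "is_name", "level_conc", "analyte_area", "is_area"}
    if missing := required - set(df.columns):
        raise SchemaError(f"calibration table missing columns {sorted(missing)}")
    curves = {}
    for analyte, grp in df.groupby("analyte", sort=True):
        levels = [
            (row["level_conc"], normalize_area(row["analyte_area"], row["is_area"]))
            for _, row in grp.iterrows()
        ]
        curves[str(analyte)] = fit_calibration(
            levels, analyte=str(analyte), is_name=str(grp["is_name"].iloc[0])
        )
    return curves
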