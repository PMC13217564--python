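"""Concentration-response evaluation and bioanalytical-equivalent (BEQ) arithmetic.

This module evaluates reporter-gene bioassay data (AhR CALUX style) into
potency metrics and carries all equivalence arithmetic of the iceberg-model
workflow:

* enrichment bookkeeping REF = EF x DF,
* EC10 / IC10 / specificity-ratio estimation from concentration-response
  series,
* B[a]P-equivalent concentrations of whole extracts (BEQ_bio), chemical
  ledgers (BEQ_chem = sum REP_i * C_i) and their ratio (the explained
  fraction),
* effect-based trigger values transferred from water to sediment via Koc,
* concentration-addition mixture potency prediction.

Concentration units are carried as explicit tags and checked at every
boundary; mixed-unit calls raise :class:`~edascreen.errors.UnitError`.
Canonical internal units are micromolar (or ug/L) for single chemicals and
g_sediment/L for extracts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitDomainError, UndefinedPotencyError, UnitError

__all__ = [
    "DoseResponseSeries",
    "EnrichmentSpec",
    "PotencySummary",
    "SampleBEQ",
    "ChemicalPotency",
    "SedimentBenchmark",
    "MixtureSpec",
    "DistributionRatio",
    "relative_enrichment_factor",
    "fit_potency",
    "specificity_ratio",
    "bap_eq_bio",
    "tcdd_to_bap_eq",
    "rep",
    "bap_eq_chem",
    "contribution",
    "ebt_sediment",
    "d_sed_w",
    "toc_normalize",
    "ca_mixture_ec10",
    "fractionation_recovery",
    "designed_fraction_count",
    "blank_corrected_beq",
    "read_plate_csv",
    "beq_table",
]

# unit tag -> factor into the canonical unit of its family
_EXTRACT_UNITS = {"g/L": 1.0, "g/mL": 1e3}  # canonical g_sed/L
_MASS_CONC_UNITS = {"ug/L": 1.0, "mg/L": 1e3}  # canonical ug/L
_MOLAR_UNITS = {"uM": 1.0, "nM": 1e-3, "M": 1e6}  # canonical uM


def _to_canonical(value: float, unit: str) -> float:
    for table in (_EXTRACT_UNITS, _MASS_CONC_UNITS, _MOLAR_UNITS):
        if unit in table:
            return value * table[unit]
    raise UnitError(f"unknown concentration unit tag {unit!r}")


def _same_family(unit_a: str, unit_b: str) -> bool:
    for table in (_EXTRACT_UNITS, _MASS_CONC_UNITS, _MOLAR_UNITS):
        if unit_a in table or unit_b in table:
            return unit_a in table and unit_b in table
    raise UnitError(f"unknown concentration unit tags {unit_a!r}, {unit_b!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseSeries:
    """One concentration-response series of a sample, chemical or fraction.

    ``concentrations`` are expressed in the tagged ``unit`` (REF in
    g_sed,dw/mL for extracts, molar or mass concentration for single
    chemicals); ``effect_pct`` is % of the positive-control maximum and
    ``cytotox_pct`` absolute % cytotoxicity.
    """

    sample_id: str
    concentrations: np.ndarray
    effect_pct: np.ndarray
    unit: str
    cytotox_pct: np.ndarray | None = None
    replicate_id: int = 0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.effect_pct = np.asarray(self.effect_pct, dtype=float)
        if self.cytotox_pct is not None:
            self.cytotox_pct = np.asarray(self.cytotox_pct, dtype=float)
            if self.cytotox_pct.shape != self.concentrations.shape:
                raise ValueError("cytotox_pct length mismatch")
        if self.concentrations.ndim != 1:
            raise ValueError("concentrations must be 1-D")
        if self.effect_pct.shape != self.concentrations.shape:
            raise ValueError("effect_pct length mismatch")
        if not np.all(self.concentrations > 0):
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.isfinite(self.effect_pct)):
            raise ValueError("effect_pct must be finite")
        _to_canonical(1.0, self.unit)  # validates tag


@dataclass(frozen=True)
class EnrichmentSpec:
    """Enrichment bookkeeping for a sediment extract in the bioassay.

    EF is the enrichment factor of the methanolic stock (g_sed,dw per mL
    methanol), DF the dilution factor into the bioassay medium, and REF
    their product (g_sed,dw per mL bioassay medium).
    """

    ef: float
    df: float

    def __post_init__(self):
        if self.ef <= 0 or self.df <= 0:
            raise ValueError("EF and DF must be positive")

    @property
    def ref(self) -> float:
        return relative_enrichment_factor(self.ef, self.df)


@dataclass
class PotencySummary:
    """Fitted potency metrics for a single series.

    ``ec10`` and ``ic10`` share the series unit; ``sr`` = IC10/EC10 is
    dimensionless. Missing quantities are ``None`` (never 0 or inf) and the
    reason is recorded in ``notes``.
    """

    ec10: float | None
    ic10: float | None
    sr: float | None
    slope: float | None
    fit_diagnostics: float | None
    unit: str
    inactive: bool = False
    notes: list[str] = field(default_factory=list)


@dataclass
class SampleBEQ:
    """Per-sample B[a]P-equivalent summary on dry-weight and OC basis."""

    sample_id: str
    beq_bio_dw: float  # ug B[a]P / g_sed,dw
    toc_fraction: float  # g_OC / g_sed,dw
    beq_bio_oc: float = field(init=False)
    tcdd_eq: float | None = None
    d_sed_w: float | None = None
    ebt_exceedance: float | None = None

    def __post_init__(self):
        if self.beq_bio_dw < 0:
            raise ValueError("BEQ must be non-negative")
        self.beq_bio_oc = toc_normalize(self.beq_bio_dw, self.toc_fraction)


@dataclass(frozen=True)
class ChemicalPotency:
    """A chemical's EC10 (tagged unit) and relative effect potency vs B[a]P."""

    name: str
    structure_id: str
    ec10: float
    unit: str
    rep: float | None = None

    def __post_init__(self):
        if self.ec10 <= 0:
            raise ValueError("EC10 must be positive")
        _to_canonical(1.0, self.unit)


@dataclass(frozen=True)
class SedimentBenchmark:
    """Effect-based trigger value transferred from water to sediment via Koc."""

    log_koc: float  # log10(L/kg_OC)
    ebt_water: float  # ug B[a]P / L

    @property
    def ebt_sediment(self) -> float:
        return ebt_sediment(self.log_koc, self.ebt_water)


@dataclass
class MixtureSpec:
    """A designed mixture: components with mass/molar fractions summing to 1."""

    components: list[tuple[ChemicalPotency, float]]

    def __post_init__(self):
        total = sum(p for _, p in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {total}, expected 1")
        units = {c.unit for c, _ in self.components}
        if len(units) > 1:
            raise UnitError(f"mixture components carry mixed units {units}")


class DistributionRatio(NamedTuple):
    ratio: float
    log10: float


# ---------------------------------------------------------------------------
# enrichment and potency fitting
# ---------------------------------------------------------------------------


def relative_enrichment_factor(ef: float, df: float) -> float:
    """REF = EF x DF, the sediment-equivalent concentration in the bioassay.

    Parameters are the enrichment factor of the extract (g_sed,dw/mL
    methanol) and the dimensionless dilution factor into the medium; the
    result is in g_sed,dw/mL bioassay medium.
    """
    if ef <= 0 or df <= 0:
        raise ValueError("EF and DF must be positive")
    return ef * df


def _origin_slope(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float]:
    """Least-squares slope through the origin and uncentered R^2."""
    slope = float(np.dot(conc, resp) / np.dot(conc, conc))
    ss_res = float(np.sum((resp - slope * conc) ** 2))
    ss_tot = float(np.sum(resp**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return slope, r2


def _loglogistic_ecx(conc, resp, threshold):
    def hill(c, top, ec50, h):
        return top / (1.0 + (ec50 / c) ** h)

    p0 = (max(resp.max(), 20.0), float(np.median(conc)), 1.0)
    popt, _ = curve_fit(hill, conc, resp, p0=p0, maxfev=20000)
    top, ec50, h = popt
    if top <= threshold or h <= 0:
        return None, None
    ecx = ec50 * (top / threshold - 1.0) ** (-1.0 / h)
    pred = hill(conc, *popt)
    ss_res = float(np.sum((resp - pred) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(ecx), r2


def fit_potency(
    series: DoseResponseSeries,
    effect_threshold: float = 10.0,
    linear_range_max: float = 30.0,
    model: str = "linear",
) -> PotencySummary:
    """Estimate EC10, IC10 and the specificity ratio from one series.

    The default model fits a straight line through the origin on the
    low-effect region (points with effect <= ``linear_range_max`` %); the
    effect concentration follows as EC10 = ``effect_threshold`` / slope.
    IC10 is derived analogously from the cytotoxicity trace at absolute 10%,
    but only when cytotoxicity actually reaches the threshold within the
    tested range; otherwise IC10 and SR are reported missing. A four-
    parameter-free log-logistic fit (``model="loglogistic"``) is available
    for full curves.
    """
    if len(series.concentrations) < 4:
        raise FitDomainError("need at least 4 concentration levels")
    order = np.argsort(series.concentrations)
    conc = series.concentrations[order]
    eff = series.effect_pct[order]
    notes: list[str] = []

    if model == "loglogistic":
        ec10, r2 = _loglogistic_ecx(conc, eff, effect_threshold)
        slope = None
        if ec10 is None:
            notes.append("log-logistic top below threshold; inactive")
            return PotencySummary(None, None, None, None, r2, series.unit, True, notes)
    elif model == "linear":
        mask = eff <= linear_range_max
        if not mask.any():
            raise FitDomainError(
                f"no effects at or below the {linear_range_max}% linear range"
            )
        slope, r2 = _origin_slope(conc[mask], eff[mask])
        if slope <= 0:
            notes.append("non-positive slope; series inactive")
            return PotencySummary(None, None, None, slope, r2, series.unit, True, notes)
        ec10 = effect_threshold / slope
    else:
        raise ValueError(f"unknown model {model!r}")

    ic10 = None
    if series.cytotox_pct is not None:
        tox = series.cytotox_pct[order]
        if np.nanmax(tox) < effect_threshold:
            notes.append("no cytotoxicity observed")
        else:
            mask_t = tox <= linear_range_max
            if mask_t.any():
                slope_t, _ = _origin_slope(conc[mask_t], tox[mask_t])
                if slope_t > 0:
                    ic10 = effect_threshold / slope_t
    else:
        notes.append("no cytotoxicity observed")

    sr = specificity_ratio(ic10, ec10, notes=notes)
    return PotencySummary(ec10, ic10, sr, slope, r2, series.unit, False, notes)


def specificity_ratio(
    ic10: float | None, ec10: float | None, notes: list[str] | None = None
) -> float | None:
    """SR = IC10/EC10; large values mean activation well below cytotoxicity."""
    if ec10 is None or not math.isfinite(ec10):
        raise UndefinedPotencyError("EC10 missing; specificity ratio undefined")
    if ec10 <= 0:
        raise ValueError("EC10 must be positive")
    if ic10 is None:
        if notes is not None and "no cytotoxicity observed" not in notes:
            notes.append("no cytotoxicity observed")
        return None
    return ic10 / ec10


# ---------------------------------------------------------------------------
# equivalence arithmetic
# ---------------------------------------------------------------------------


def bap_eq_bio(
    ec10_bap: float,
    ec10_sample: float,
    bap_unit: str = "ug/L",
    sample_unit: str = "g/L",
) -> float:
    """Bioassay-derived B[a]P-equivalents of an extract, ug_B[a]P/g_sed,dw.

    BEQ_bio = EC10(B[a]P) / EC10(extract): the more potent the extract (the
    lower its EC10 in sediment-equivalents), the higher the BEQ.
    """
    if ec10_bap <= 0 or ec10_sample <= 0:
        raise ValueError("EC10 values must be positive")
    if bap_unit not in _MASS_CONC_UNITS:
        raise UnitError(f"EC10(B[a]P) must carry a mass/volume unit, got {bap_unit!r}")
    if sample_unit not in _EXTRACT_UNITS:
        raise UnitError(f"extract EC10 must carry g_sed/volume unit, got {sample_unit!r}")
    return _to_canonical(ec10_bap, bap_unit) / _to_canonical(ec10_sample, sample_unit)


def tcdd_to_bap_eq(tcdd_eq: float, ec10_bap: float, ec10_tcdd: float,
                   unit: str = "ug/L", tcdd_unit: str = "ug/L") -> float:
    """Convert a TCDD-equivalent into a B[a]P-equivalent via the EC10 ratio."""
    if min(tcdd_eq, ec10_bap, ec10_tcdd) <= 0:
        raise ValueError("all inputs must be positive")
    if not _same_family(unit, tcdd_unit):
        raise UnitError(f"EC10 units {unit!r} and {tcdd_unit!r} are incompatible")
    return tcdd_eq * _to_canonical(ec10_bap, unit) / _to_canonical(ec10_tcdd, tcdd_unit)


def rep(ec10_bap: float, ec10_chemical: float,
        bap_unit: str = "uM", chem_unit: str = "uM") -> float:
    """Relative effect potency vs benzo[a]pyrene: REP = EC10(B[a]P)/EC10(chem)."""
    if ec10_bap <= 0 or ec10_chemical <= 0:
        raise ValueError("EC10 values must be positive")
    if not _same_family(bap_unit, chem_unit):
        raise UnitError(f"units {bap_unit!r} and {chem_unit!r} are incompatible")
    return _to_canonical(ec10_bap, bap_unit) / _to_canonical(ec10_chemical, chem_unit)


def bap_eq_chem(
    ledger: Sequence[tuple],
    censored_policy: str = "zero",
) -> float:
    """Chemically explained equivalents: BEQ_chem = sum REP_i * C_i.

    Ledger entries are ``(rep, concentration)`` or
    ``(rep, concentration, censored, mdl)`` with concentrations in
    ug/g_sed,dw. Censored (<MDL) entries contribute 0 under the default
    policy or REP * MDL/2 under ``censored_policy="half_mdl"``.
    """
    if censored_policy not in {"zero", "half_mdl"}:
        raise ValueError(f"unknown censoring policy {censored_policy!r}")
    total = 0.0
    for entry in ledger:
        r, c, *rest = entry
        censored = rest[0] if rest else False
        mdl = rest[1] if len(rest) > 1 else None
        if c < 0:
            raise ValueError("negative concentration in ledger")
        if censored:
            if censored_policy == "half_mdl" and mdl is not None:
                total += r * mdl / 2.0
        else:
            total += r * c
    return total


def contribution(beq_chem: float, beq_bio: float) -> float:
    """Explained fraction of the observed effect, in percent."""
    if beq_bio <= 0:
        raise ValueError("BEQ_bio must be positive")
    return 100.0 * beq_chem / beq_bio


def ebt_sediment(log_koc: float, ebt_water: float) -> float:
    """Transfer a water trigger value (ug/L) to sediment (ug/g_OC) via Koc.

    EBT(sediment) = Koc x EBT(water); with Koc in L/kg_OC the product is
    ug/kg_OC, hence the division by 1000 to ug/g_OC.
    """
    if ebt_water < 0:
        raise ValueError("EBT(water) must be non-negative")
    return 10.0**log_koc * ebt_water / 1000.0


def d_sed_w(beq_sediment: float, beq_water: float) -> DistributionRatio:
    """Sediment/water distribution ratio of the bio-derived equivalents."""
    if beq_water <= 0:
        raise ValueError("water BEQ must be positive")
    ratio = beq_sediment / beq_water
    return DistributionRatio(ratio, math.log10(ratio) if ratio > 0 else -math.inf)


def toc_normalize(beq_dw: float, toc_fraction: float) -> float:
    """Express a dry-weight BEQ per gram organic carbon."""
    if not 0 < toc_fraction <= 1:
        raise ValueError("TOC fraction must be in (0, 1]")
    return beq_dw / toc_fraction


def ca_mixture_ec10(mixture: "MixtureSpec | Sequence[tuple[float, float]]") -> float:
    """Concentration-addition EC10 of a mixture: 1/EC10_mix = sum p_i/EC10_i.

    Accepts a :class:`MixtureSpec` or a bare sequence of
    ``(fraction, ec10)`` pairs. Reduces to the component EC10 for a
    single-component "mixture" and is permutation invariant.
    """
    if isinstance(mixture, MixtureSpec):
        pairs = [(p, comp.ec10) for comp, p in mixture.components]
    else:
        pairs = [(float(p), float(e)) for p, e in mixture]
        total = sum(p for p, _ in pairs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
    for _, e in pairs:
        if not math.isfinite(e) or e <= 0:
            raise UndefinedPotencyError("all component EC10 values must be finite and positive")
    return 1.0 / sum(p / e for p, e in pairs)


def fractionation_recovery(beq_recombined: float, beq_unfractionated: float) -> float:
    """Recovery (%) of activity in recombined fractions vs the whole extract."""
    if beq_unfractionated <= 0:
        raise ValueError("unfractionated BEQ must be positive")
    return 100.0 * beq_recombined / beq_unfractionated


def designed_fraction_count(elution_minutes: float = 24.0, fraction_seconds: float = 18.0) -> int:
    """Number of fractions designed for an elution window at a fixed width."""
    if elution_minutes <= 0 or fraction_seconds <= 0:
        raise ValueError("durations must be positive")
    return int(round(elution_minutes * 60.0 / fraction_seconds))


def blank_corrected_beq(
    sample_beq: float, blank_beq: float, subtract_threshold_pct: float = 10.0
) -> tuple[float, float]:
    """Blank policy: report blank as % of sample; subtract only if above threshold.

    Returns ``(corrected_beq, blank_pct)``.
    """
    if sample_beq <= 0:
        raise ValueError("sample BEQ must be positive")
    blank_pct = 100.0 * blank_beq / sample_beq
    corrected = sample_beq - blank_beq if blank_pct > subtract_threshold_pct else sample_beq
    return corrected, blank_pct


# ---------------------------------------------------------------------------
# i/o helpers
# ---------------------------------------------------------------------------


def read_plate_csv(path) -> list[DoseResponseSeries]:
    """Read a plate export (sample_id, replicate, concentration, unit,
    effect_pct, cytotox_pct) into one series per (sample, replicate)."""
    df = pd.read_csv(path)
    required = {"sample_id", "replicate", "concentration", "unit", "effect_pct"}
    missing = required - set(df.columns)
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"plate export missing columns {sorted(missing)}")
    out = []
    for (sid, repid), grp in df.groupby(["sample_id", "replicate"], sort=True):
        units = grp["unit"].unique()
        if len(units) != 1:
            raise UnitError(f"series {sid}/{repid} mixes units {list(units)}")
        tox = grp["cytotox_pct"].to_numpy() if "cytotox_pct" in grp else None
        out.append(
            DoseResponseSeries(
                sample_id=str(sid),
                concentrations=grp["concentration"].to_numpy(),
                effect_pct=grp["effect_pct"].to_numpy(),
                unit=str(units[0]),
                cytotox_pct=tox,
                replicate_id=int(repid),
            )
        )
    return out


def beq_table(
    series_list: Sequence[DoseResponseSeries],
    ec10_bap: float,
    toc_by_sample: dict[str, float] | None = None,
    benchmark: SedimentBenchmark | None = None,
    bap_unit: str = "ug/L",
) -> pd.DataFrame:
    """Per-sample summary table: EC10, IC10, SR, BEQ_dw, BEQ_OC, EBT exceedance.

    Extract series must be in sediment-equivalent units (g/L or g/mL).
    """
    rows = []
    for s in series_list:
        summ = fit_potency(s)
        row = {
            "sample_id": s.sample_id,
            "replicate": s.replicate_id,
            "ec10": summ.ec10,
            "ic10": summ.ic10,
            "sr": summ.sr,
            "unit": s.unit,
        }
        if summ.ec10 is not None:
            row["beq_dw"] = bap_eq_bio(ec10_bap, summ.ec10, bap_unit, s.unit)
            toc = (toc_by_sample or {}).get(s.sample_id)
            if toc is not None:
                row["beq_oc"] = toc_normalize(row["beq_dw"], toc)
                if benchmark is not None:
                    row["ebt_exceedance"] = row["beq_oc"] / benchmark.ebt_sediment
        rows.append(row)
    return pd.DataFrame(rows)
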