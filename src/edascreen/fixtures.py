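"""Seeded synthetic ground-truth worlds for exercising the whole pipeline.

Every input the workflow consumes — spectral library, GC-HRMS feature
tables with internal-standard areas and blanks, alkane ladder, bioassay
plate exports, calibration series, descriptor matrices with activity
labels — is generated here with known planted truth, so the pipeline's
recoveries can be checked mechanically and offline.

The spectra are synthetic peak sets (vector geometry is all the matching
uses), descriptors are Gaussian/uniform draws with a planted activity rule
(active iff d1 + d2 > 1) and a planted log-linear potency surface; none of
this emulates real EI fragmentation or real descriptor physics, which is
exactly why the matching and modeling code cannot overfit to it.

Default noise levels are the desk-scale study conditions: 1% absolute
effect noise on bioassay responses, 2% relative noise on calibration and
feature areas, 0.2 log10 units on the potency surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bioassay import DoseResponseSeries, bap_eq_bio, fit_potency, rep as rep_ratio
from .iceberg import SampleLedger, build_ledger
from .quant import (
    assign_internal_standard,
    default_is_map,
    fit_calibration,
    normalize_area,
    quantify,
)
from .spectra import AlkaneLadder, Feature, LibraryRecord, MassSpectrum, search_library

__all__ = [
    "SyntheticWorld",
    "gen_world",
    "gen_crc",
    "gen_classification_data",
    "gen_regression_data",
    "explained_fraction_pipeline",
]

EC10_BAP_UM = 108.0  # reference molar potency of B[a]P in the reporter assay
EC10_BAP_UG_L = 2.67  # reference mass-concentration potency (carried separately)


def gen_crc(
    true_ec10: float,
    noise_sd: float = 1.0,
    n_levels: int = 11,
    seed: int = 0,
    unit: str = "uM",
    sample_id: str = "chem",
    cytotox_onset: float | None = None,
    dilution: float = 2.0,
) -> DoseResponseSeries:
    """Simulate a concentration-response series with a known EC10.

    The effect is linear through the origin at low effect (10% at
    ``true_ec10``), capped at 100%; concentrations form a geometric
    dilution series (factor ``dilution``, 11 levels by default) whose top
    level sits at 25% effect, inside the linear fit window. When
    ``cytotox_onset`` is given, cytotoxicity rises linearly with
    IC10 = onset x EC10 and the tested range is extended to reach it.
    """
    if true_ec10 <= 0:
        raise ValueError("true EC10 must be positive")
    rng = np.random.default_rng(seed)
    c_max = 2.5 * true_ec10
    if cytotox_onset is not None:
        c_max = max(c_max, 1.2 * cytotox_onset * true_ec10)
    conc = c_max / dilution ** np.arange(n_levels)[::-1]
    effect = np.minimum(10.0 * conc / true_ec10, 100.0)
    effect = effect + rng.normal(0.0, noise_sd, n_levels)
    tox = None
    if cytotox_onset is not None:
        ic10 = cytotox_onset * true_ec10
        tox = np.clip(10.0 * conc / ic10, 0.0, 100.0) + rng.normal(0.0, noise_sd, n_levels)
        tox = np.maximum(tox, 0.0)
    return DoseResponseSeries(sample_id, conc, effect, unit, cytotox_pct=tox)


def gen_classification_data(
    n: int = 2000, n_descriptors: int = 10, seed: int = 7
) -> tuple[pd.DataFrame, np.ndarray]:
    """Descriptor matrix with the planted rule: active iff d1 + d2 > 1."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(0.0, 1.0, size=(n, n_descriptors)),
        columns=[f"d{i + 1}" for i in range(n_descriptors)],
    )
    y = (X["d1"] + X["d2"] > 1.0).to_numpy().astype(int)
    return X, y


def gen_regression_data(
    n: int = 400, n_descriptors: int = 10, noise_sd: float = 0.2, seed: int = 7
) -> tuple[pd.DataFrame, np.ndarray]:
    """Actives with a planted log-linear potency surface; returns EC10 in uM.

    log10 EC10 = 2.5 - 1.5 d1 - 1.0 d2 + N(0, noise_sd).
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(0.0, 1.0, size=(n, n_descriptors)),
        columns=[f"d{i + 1}" for i in range(n_descriptors)],
    )
    log_ec10 = 2.5 - 1.5 * X["d1"] - 1.0 * X["d2"] + rng.normal(0.0, noise_sd, n)
    return X, 10.0**log_ec10.to_numpy()


def _synthetic_spectrum(rng: np.random.Generator) -> MassSpectrum:
    n_peaks = int(rng.integers(6, 11))
    mz = np.sort(rng.choice(np.arange(50, 450), size=n_peaks, replace=False).astype(float))
    mz += np.round(rng.uniform(-0.004, 0.004, n_peaks), 4)
    intensity = rng.uniform(50.0, 999.0, n_peaks)
    return MassSpectrum(mz, intensity)


def _synthetic_inchikey(rng: np.random.Generator) -> str:
    letters = "".join(rng.choice(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"), size=14))
    tail = "".join(rng.choice(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"), size=10))
    return f"{letters}-{tail}SA-N"  # synthetic stand-in, not a real InChIKey


@dataclass
class SyntheticWorld:
    """A fully reproducible bundle of pipeline inputs plus planted truth."""

    seed: int
    explained_target: float
    library: list[LibraryRecord]
    ladder: AlkaneLadder
    descriptors: pd.DataFrame  # indexed by structure_id
    truth: pd.DataFrame  # structure_id, name, active, ec10_um, rep, ri
    features: list[Feature]
    blank_areas: pd.DataFrame  # feature_id + area_blank* columns
    is_areas: dict[str, dict[str, float]]  # sample -> is_name -> area
    chemical_series: dict[str, list[DoseResponseSeries]]  # structure_id -> uM replicates
    bap_series_molar: list[DoseResponseSeries]
    bap_series_mass: list[DoseResponseSeries]
    extract_series: dict[str, list[DoseResponseSeries]]  # sample -> g/L replicates
    calibration: pd.DataFrame  # analyte, is_name, level_conc, analyte_area, is_area
    planted_concentrations: dict[str, dict[str, float]]  # sample -> structure -> ug/g
    planted_beq_bio: dict[str, float]
    sample_mass_g: float = 1.0
    extract_volume_ml: float = 1.0
    rt_by_structure: dict[str, float] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        """Materialize the world in the on-disk formats the pipeline reads."""
        from .bioassay import read_plate_csv  # noqa: F401  (format contract)
        from .spectra import write_feature_table, write_msp

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_msp(self.library, out / "library.msp")
        write_feature_table(self.features, out / "features.tsv")
        pd.DataFrame(
            [(n, rt) for n, rt in self.ladder.entries], columns=["n", "rt"]
        ).to_csv(out / "alkanes.csv", index=False)
        self.calibration.to_csv(out / "calibration.csv", index=False)
        rows = []
        for sid, replicates in {
            **self.extract_series,
            "BaP_mass": self.bap_series_mass,
            "BaP_molar": self.bap_series_molar,
            **self.chemical_series,
        }.items():
            for series in replicates:
                for c, e in zip(series.concentrations, series.effect_pct):
                    rows.append(
                        {
                            "sample_id": sid,
                            "replicate": series.replicate_id,
                            "concentration": c,
                            "unit": series.unit,
                            "effect_pct": e,
                            "cytotox_pct": np.nan,
                        }
                    )
        pd.DataFrame(rows).to_csv(out / "plate.csv", index=False)
        self.descriptors.to_csv(out / "descriptors.csv")
        self.truth.to_csv(out / "truth_labels.csv", index=False)
        sidecar = {
            "seed": self.seed,
            "explained_target": self.explained_target,
            "planted_beq_bio": self.planted_beq_bio,
            "planted_concentrations": self.planted_concentrations,
        }
        (out / "truth.json").write_text(json.dumps(sidecar, indent=1))


def gen_world(
    n_active: int = 30,
    n_inactive: int = 30,
    n_samples: int = 3,
    explained_target: float = 0.3,
    seed: int = 7,
    effect_noise_sd: float = 1.0,
    area_noise_rel: float = 0.02,
) -> SyntheticWorld:
    """Generate a complete synthetic study with a planted explained fraction.

    Each sample carries planted concentrations of a subset of the active
    chemicals; the extract's dose-response series is constructed so that
    its bioassay-derived BEQ equals the planted chemical BEQ divided by
    ``explained_target``. Same seed, same world, byte for byte.
    """
    if n_active <= 0 or n_inactive <= 0 or n_samples <= 0:
        raise ValueError("counts must be positive")
    if not 0 < explained_target <= 1:
        raise ValueError("explained_target must be in (0, 1]")
    rng = np.random.default_rng(seed)

    # --- structures, descriptors, planted potency -------------------------
    n_desc = 10
    records, rows, desc_rows, structure_ids = [], [], [], []
    n_act = n_inact = 0
    ladder = AlkaneLadder([(n, 1.0 + 0.8 * (n - 8)) for n in range(8, 33)])
    while n_act < n_active or n_inact < n_inactive:
        d = rng.uniform(0.0, 1.0, n_desc)
        active = d[0] + d[1] > 1.0
        if active and n_act >= n_active:
            continue
        if not active and n_inact >= n_inactive:
            continue
        i = len(structure_ids)
        sid = _synthetic_inchikey(rng)
        name = f"compound_{i:03d}"
        ri = float(rng.uniform(900, 3100))
        ec10_um = None
        rep_val = None
        if active:
            log_ec10 = 2.5 - 1.5 * d[0] - 1.0 * d[1] + rng.normal(0.0, 0.2)
            ec10_um = 10.0**log_ec10
            rep_val = EC10_BAP_UM / ec10_um
            n_act += 1
        else:
            n_inact += 1
        structure_ids.append(sid)
        desc_rows.append(d)
        records.append(
            LibraryRecord(name=name, spectrum=_synthetic_spectrum(rng), inchikey=sid, ri=ri)
        )
        rows.append(
            {
                "structure_id": sid,
                "name": name,
                "active": active,
                "ec10_um": ec10_um,
                "rep": rep_val,
                "ri": ri,
            }
        )
    truth = pd.DataFrame(rows)
    descriptors = pd.DataFrame(
        desc_rows, index=structure_ids, columns=[f"d{i + 1}" for i in range(n_desc)]
    )
    descriptors.index.name = "structure_id"

    # --- per-chemical bioassay series (for measured REPs) -----------------
    # each assay is run in triplicate, matching reporter-assay practice
    n_reps = 3

    def _replicates(ec10, unit, sample_id):
        out = []
        for r in range(n_reps):
            series = gen_crc(
                ec10, noise_sd=effect_noise_sd, seed=int(rng.integers(2**31)),
                unit=unit, sample_id=sample_id,
            )
            series.replicate_id = r
            out.append(series)
        return out

    chemical_series = {
        row["structure_id"]: _replicates(row["ec10_um"], "uM", row["structure_id"])
        for _, row in truth[truth["active"]].iterrows()
    }
    bap_series_molar = _replicates(EC10_BAP_UM, "uM", "BaP")
    bap_series_mass = _replicates(EC10_BAP_UG_L, "ug/L", "BaP")

    # --- planted sample composition and extract series --------------------
    active_ids = truth.loc[truth["active"], "structure_id"].tolist()
    rep_by_id = dict(zip(truth["structure_id"], truth["rep"]))
    planted, beq_bio_planted, extract_series = {}, {}, {}
    sample_names = [f"S{k + 1}" for k in range(n_samples)]
    for s in sample_names:
        n_present = max(3, int(round(0.6 * len(active_ids))))
        present = list(rng.choice(active_ids, size=n_present, replace=False))
        conc = {sid: float(np.exp(rng.normal(0.0, 1.0))) for sid in present}
        planted[s] = conc
        beq_chem = sum(rep_by_id[sid] * c for sid, c in conc.items())  # ug/g if REP vs ug-scale
        # scale so chemical BEQ sits in the low ug/g range typical of sediments
        scale = 10.0 / beq_chem
        planted[s] = {sid: c * scale for sid, c in conc.items()}
        beq_chem *= scale
        beq_bio = beq_chem / explained_target
        beq_bio_planted[s] = beq_bio
        ec10_sample_g_l = EC10_BAP_UG_L / beq_bio  # from BEQ_bio = EC10(BaP)/EC10(extract)
        extract_series[s] = _replicates(ec10_sample_g_l, "g/L", s)

    # --- chromatography: features, areas, blanks, calibration -------------
    rt_by_structure = {}
    ri_by_id = dict(zip(truth["structure_id"], truth["ri"]))
    rec_by_id = {r.inchikey: r for r in records}
    is_map = default_is_map()
    is_names = [w[2] for w in is_map.windows]
    is_areas = {
        s: {name: 1e6 * float(np.exp(rng.normal(0.0, 0.1))) for name in is_names}
        for s in sample_names
    }
    response = {sid: float(rng.uniform(0.5, 2.0)) for sid in structure_ids}
    present_any = sorted({sid for s in sample_names for sid in planted[s]})
    features, blank_rows = [], []
    cal_rows = []
    entries = ladder.entries
    rt_lo, rt_hi = entries[0][1], entries[-1][1]
    for sid in present_any:
        ri = ri_by_id[sid]
        # invert the (linear) ladder to an RT; clamp inside the ladder range
        n_frac = ri / 100.0
        rt = float(np.clip(1.0 + 0.8 * (n_frac - 8.0), rt_lo + 1e-6, rt_hi - 1e-6))
        rt_by_structure[sid] = rt
        is_name = assign_internal_standard(rt, is_map)
        areas = {}
        for s in sample_names:
            c = planted[s].get(sid)
            if c is None:
                areas[s] = 0.0
                continue
            vial = c * 1.0 / 1.0  # ug/mL at 1 g sample, 1 mL extract
            noise = 1.0 + rng.normal(0.0, area_noise_rel)
            areas[s] = response[sid] * vial * is_areas[s][is_name] * noise
        rec = rec_by_id[sid]
        features.append(
            Feature(
                feature_id=f"F_{sid[:6]}",
                rt=rt,
                spectrum=MassSpectrum(rec.spectrum.mz.copy(), rec.spectrum.intensity.copy()),
                model_ion_mz=float(rec.spectrum.mz[np.argmax(rec.spectrum.intensity)]),
                ri=ri,
                area_by_sample=areas,
            )
        )
        blank_rows.append(
            {"feature_id": f"F_{sid[:6]}", "area_blank1": float(rng.uniform(0, 100.0))}
        )
        # calibration series on the IS-normalized scale
        for level in (0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0):
            is_area = 1e6
            noise = 1.0 + rng.normal(0.0, area_noise_rel)
            cal_rows.append(
                {
                    "analyte": sid,
                    "is_name": is_name,
                    "level_conc": level,
                    "analyte_area": response[sid] * level * is_area * noise,
                    "is_area": is_area,
                }
            )

    return SyntheticWorld(
        seed=seed,
        explained_target=explained_target,
        library=records,
        ladder=ladder,
        descriptors=descriptors,
        truth=truth,
        features=features,
        blank_areas=pd.DataFrame(blank_rows),
        is_areas=is_areas,
        chemical_series=chemical_series,
        bap_series_molar=bap_series_molar,
        bap_series_mass=bap_series_mass,
        extract_series=extract_series,
        calibration=pd.DataFrame(cal_rows),
        planted_concentrations=planted,
        planted_beq_bio=beq_bio_planted,
        rt_by_structure=rt_by_structure,
    )


def explained_fraction_pipeline(world: SyntheticWorld) -> dict[str, float]:
    """Run the full desk pipeline on a synthetic world and return the
    recovered explained fraction (%) per sample.

    The chain is: library search identifies each feature; calibration
    curves (IS-normalized) quantify it; measured REPs come from the
    per-chemical and B[a]P concentration-response fits; the extract fits
    give BEQ_bio; the ledger division gives the explained fraction.
    """
    # measured potencies: geometric-mean EC10 over replicate fits
    def _ec10(replicates):
        vals = [fit_potency(s).ec10 for s in replicates]
        return float(np.exp(np.mean(np.log(vals))))

    ec10_bap_um = _ec10(world.bap_series_molar)
    ec10_bap_ugl = _ec10(world.bap_series_mass)
    measured_rep = {
        sid: rep_ratio(ec10_bap_um, _ec10(replicates))
        for sid, replicates in world.chemical_series.items()
    }

    # calibration curves per analyte
    curves = {}
    for analyte, grp in world.calibration.groupby("analyte"):
        levels = [
            (r["level_conc"], normalize_area(r["analyte_area"], r["is_area"]))
            for _, r in grp.iterrows()
        ]
        curves[analyte] = fit_calibration(
            levels,
            analyte=str(analyte),
            is_name=str(grp["is_name"].iloc[0]),
            weighting="1/x",  # relative area noise across a wide geometric range
        )

    is_map = default_is_map()
    out = {}
    for sample, replicates in world.extract_series.items():
        ec10_sample = _ec10(replicates)
        beq_bio = bap_eq_bio(ec10_bap_ugl, ec10_sample, "ug/L", "g/L")
        quantified = []
        for feat in world.features:
            area = feat.area_by_sample.get(sample, 0.0)
            if area <= 0:
                continue
            hits = search_library(feat, world.library, top_k=1)
            if not hits:
                continue
            sid = hits[0].record.structure_id
            if sid not in curves:
                continue
            is_name = assign_internal_standard(feat.rt, is_map)
            norm = normalize_area(area, world.is_areas[sample][is_name])
            quantified.append(
                quantify(
                    curves[sid],
                    norm,
                    world.sample_mass_g,
                    world.extract_volume_ml,
                    sample_id=sample,
                    structure_id=sid,
                )
            )
        ledger: SampleLedger = build_ledger(
            quantified, measured_rep, beq_bio, sample_id=sample
        )
        out[sample] = ledger.explained_fraction
    return out
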