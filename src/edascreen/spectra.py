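"""GC-EI spectral data, Kovats retention indices and library matching.

Deconvoluted EI spectra are scored against reference library records with a
weighted-cosine match factor (MF) and its reverse variant (RMF, ignoring
query peaks absent from the reference), the classical 0-1000 scale of EI
library search. Candidate hits are filtered on MF, RMF and the difference in
van den Dool-Kratz retention index, and features whose top candidates
coincide are collapsed into isomer groups.

MSP reading/writing is delegated to :mod:`matchms`; spectra are normalized
to a base peak of 999 on ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import MSPParseError, SchemaError

__all__ = [
    "MassSpectrum",
    "Feature",
    "LibraryRecord",
    "AlkaneLadder",
    "CandidateHit",
    "IsomerGroup",
    "read_msp",
    "write_msp",
    "kovats_ri",
    "match_factor",
    "reverse_match_factor",
    "search_library",
    "prefilter_features",
    "group_isomer_features",
    "read_feature_table",
    "write_feature_table",
    "read_alkane_ladder",
]

BASE_PEAK = 999.0


@dataclass
class MassSpectrum:
    """A centroided EI spectrum: strictly increasing m/z with intensities.

    Intensities are rescaled so the base peak equals ``normalization``
    (999 by default, the conventional EI-library scale).
    """

    mz: np.ndarray
    intensity: np.ndarray
    normalization: float | None = BASE_PEAK

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be matching 1-D arrays")
        if len(self.mz) == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz)
            self.mz, self.intensity = self.mz[order], self.intensity[order]
            if np.any(np.diff(self.mz) <= 0):
                raise ValueError("duplicate m/z values")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        peak = self.intensity.max()
        if peak <= 0:
            raise ValueError("spectrum has no positive-intensity peak")
        if self.normalization is not None:
            self.intensity = self.intensity * (self.normalization / peak)

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Feature:
    """A deconvoluted GC-HRMS feature anchored at a retention time."""

    feature_id: str
    rt: float  # minutes
    spectrum: MassSpectrum
    model_ion_mz: float | None = None
    ri: float | None = None  # Kovats index, if an alkane ladder brackets rt
    area_by_sample: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.rt <= 0:
            raise ValueError("retention time must be positive")


@dataclass
class LibraryRecord:
    """A reference spectrum with structure identifiers and optional RI."""

    name: str
    spectrum: MassSpectrum
    smiles: str | None = None
    inchikey: str | None = None
    ri: float | None = None

    @property
    def structure_id(self) -> str:
        return self.inchikey or self.smiles or self.name


@dataclass
class AlkaneLadder:
    """Retention times of the n-alkane ladder (carbon number, rt/min)."""

    entries: list[tuple[int, float]]

    def __post_init__(self):
        self.entries = sorted((int(n), float(rt)) for n, rt in self.entries)
        ns = [n for n, _ in self.entries]
        rts = [rt for _, rt in self.entries]
        if len(self.entries) < 2:
            raise ValueError("ladder needs at least two alkanes")
        if min(ns) < 5:
            raise ValueError("carbon numbers below C5 are not supported")
        if len(set(ns)) != len(ns):
            raise ValueError("duplicate carbon numbers")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must increase with carbon number")
        gaps = [(a, b) for a, b in zip(ns, ns[1:]) if b - a > 1]
        if gaps:
            warnings.warn(f"alkane ladder has gaps between carbon numbers: {gaps}")


@dataclass
class CandidateHit:
    record: LibraryRecord
    mf: float
    rmf: float
    ri_diff: float | None
    rank: int = 0

    def __post_init__(self):
        if not (0 <= self.mf <= 1000 and 0 <= self.rmf <= 1000):
            raise ValueError("MF/RMF must lie in [0, 1000]")


@dataclass
class IsomerGroup:
    """Several features whose top library candidates coincide."""

    feature_ids: list[str]
    shared_candidates: list[str]

    def __post_init__(self):
        if len(self.feature_ids) < 2:
            raise ValueError("an isomer group needs at least 2 features")


# ---------------------------------------------------------------------------
# MSP i/o (matchms-backed)
# ---------------------------------------------------------------------------


def _validate_msp_blocks(path: Path) -> None:
    """Cheap structural pass: every Name block must carry a Num Peaks line."""
    name_line = None
    has_numpeaks = False
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            low = raw.strip().lower()
            if low.startswith(("name:", "compound_name:")):
                if name_line is not None and not has_numpeaks:
                    raise MSPParseError("record without 'Num Peaks' field", line=name_line)
                name_line, has_numpeaks = i, False
            elif low.startswith(("num peaks:", "numpeaks:", "num_peaks:")):
                has_numpeaks = True
    if name_line is not None and not has_numpeaks:
        raise MSPParseError("record without 'Num Peaks' field", line=name_line)


def read_msp(path) -> list[LibraryRecord]:
    """Read an MSP (NIST text dialect) library into :class:`LibraryRecord` s."""
    from matchms.importing import load_from_msp

    path = Path(path)
    _validate_msp_blocks(path)
    records = []
    for spec in load_from_msp(str(path), metadata_harmonization=False):
        if spec is None:
            continue
        meta = {k.lower(): v for k, v in spec.metadata.items()}
        ri = meta.get("retention_index") or meta.get("retentionindex") or meta.get("ri")
        records.append(
            LibraryRecord(
                name=str(meta.get("compound_name") or meta.get("name") or ""),
                spectrum=MassSpectrum(spec.peaks.mz, spec.peaks.intensities),
                smiles=meta.get("smiles"),
                inchikey=meta.get("inchikey"),
                ri=float(ri) if ri not in (None, "") else None,
            )
        )
    return records


def write_msp(records: Sequence[LibraryRecord], path) -> None:
    """Write records to MSP; peaks keep their stored (base-999) scale."""
    from matchms import Spectrum
    from matchms.exporting import save_as_msp

    spectra = []
    for rec in records:
        meta = {"compound_name": rec.name}
        if rec.smiles:
            meta["smiles"] = rec.smiles
        if rec.inchikey:
            meta["inchikey"] = rec.inchikey
        if rec.ri is not None:
            meta["retention_index"] = rec.ri
        spectra.append(
            Spectrum(
                mz=rec.spectrum.mz.copy(),
                intensities=rec.spectrum.intensity.copy(),
                metadata=meta,
                metadata_harmonization=False,
            )
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    save_as_msp(spectra, str(path), mode="w")


# ---------------------------------------------------------------------------
# retention indexing
# ---------------------------------------------------------------------------


def kovats_ri(rt: float, ladder: AlkaneLadder) -> float:
    """Van den Dool-Kratz retention index for a temperature-programmed run.

    RI = 100 * (n + dn * (rt - rt_n) / (rt_n+dn - rt_n)) for the ladder pair
    bracketing ``rt``; no extrapolation outside the ladder.
    """
    entries = ladder.entries
    if not entries[0][1] <= rt <= entries[-1][1]:
        raise ValueError(
            f"rt {rt} outside ladder range [{entries[0][1]}, {entries[-1][1]}]"
        )
    for (n_lo, rt_lo), (n_hi, rt_hi) in zip(entries, entries[1:]):
        if rt_lo <= rt <= rt_hi:
            frac = (rt - rt_lo) / (rt_hi - rt_lo)
            return 100.0 * (n_lo + (n_hi - n_lo) * frac)
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# spectral similarity
# ---------------------------------------------------------------------------


def _align_peaks(query: MassSpectrum, library: MassSpectrum, mz_tol: float):
    """Greedy nearest-m/z pairing within tolerance.

    Returns index pairs (iq, il) plus the unmatched indices of either side.
    """
    pairs = []
    for iq, mq in enumerate(query.mz):
        for il, ml in enumerate(library.mz):
            d = abs(mq - ml)
            if d <= mz_tol:
                pairs.append((d, iq, il))
    pairs.sort()
    used_q, used_l, matched = set(), set(), []
    for _, iq, il in pairs:
        if iq not in used_q and il not in used_l:
            matched.append((iq, il))
            used_q.add(iq)
            used_l.add(il)
    un_q = [i for i in range(len(query)) if i not in used_q]
    un_l = [i for i in range(len(library)) if i not in used_l]
    return matched, un_q, un_l


def _weights(spec: MassSpectrum, idx, intensity_exp: float, mz_exp: float) -> np.ndarray:
    idx = np.asarray(idx, dtype=int)
    return spec.intensity[idx] ** intensity_exp * spec.mz[idx] ** mz_exp


def match_factor(
    query: MassSpectrum,
    library_spectrum: MassSpectrum,
    intensity_exp: float = 0.6,
    mz_exp: float = 3.0,
    mz_tol: float = 0.01,
) -> float:
    """Weighted-cosine match factor on the 0-1000 EI-library scale.

    Peaks are paired greedily by nearest m/z within ``mz_tol``; unpaired
    peaks contribute zero on the other side. Weights are
    intensity**a * mz**b with the classical EI defaults a=0.6, b=3. The
    score is symmetric and equals 1000 iff the weighted vectors are
    parallel.
    """
    matched, un_q, un_l = _align_peaks(query, library_spectrum, mz_tol)
    if not matched:
        return 0.0
    iq = [p[0] for p in matched]
    il = [p[1] for p in matched]
    wq = _weights(query, iq, intensity_exp, mz_exp)
    wl = _weights(library_spectrum, il, intensity_exp, mz_exp)
    dot = float(np.dot(wq, wl))
    nq = float(np.dot(wq, wq) + np.sum(_weights(query, un_q, intensity_exp, mz_exp) ** 2))
    nl = float(
        np.dot(wl, wl) + np.sum(_weights(library_spectrum, un_l, intensity_exp, mz_exp) ** 2)
    )
    if nq == 0 or nl == 0:
        return 0.0
    return float(min(1000.0 * dot / np.sqrt(nq * nl), 1000.0))


def reverse_match_factor(
    query: MassSpectrum,
    library_spectrum: MassSpectrum,
    intensity_exp: float = 0.6,
    mz_exp: float = 3.0,
    mz_tol: float = 0.01,
) -> float:
    """Match factor after discarding query peaks absent from the reference.

    Ignoring query-only peaks (impurities, co-eluting fragments) can only
    raise the score, so RMF >= MF.
    """
    matched, _, un_l = _align_peaks(query, library_spectrum, mz_tol)
    if not matched:
        return 0.0
    iq = [p[0] for p in matched]
    il = [p[1] for p in matched]
    wq = _weights(query, iq, intensity_exp, mz_exp)
    wl = _weights(library_spectrum, il, intensity_exp, mz_exp)
    dot = float(np.dot(wq, wl))
    nq = float(np.dot(wq, wq))
    nl = float(
        np.dot(wl, wl) + np.sum(_weights(library_spectrum, un_l, intensity_exp, mz_exp) ** 2)
    )
    if nq == 0 or nl == 0:
        return 0.0
    return float(min(1000.0 * dot / np.sqrt(nq * nl), 1000.0))


def search_library(
    feature: Feature,
    library: Sequence[LibraryRecord],
    mf_min: float = 700.0,
    rmf_min: float = 700.0,
    ri_tol: float = 200.0,
    top_k: int | None = 5,
    **mf_kwargs,
) -> list[CandidateHit]:
    """Score a feature against the library and apply the screening thresholds.

    Candidates must exceed both match factors strictly (MF > ``mf_min``,
    RMF > ``rmf_min``) and, when both retention indices are known, fall
    strictly within the RI tolerance (|dRI| < ``ri_tol``). Hits are ranked
    by descending (MF+RMF)/2, ties by smaller RI difference then structure
    id, and truncated to ``top_k``.
    """
    if not library:
        raise ValueError("empty library")
    if feature.ri is None:
        warnings.warn(
            f"feature {feature.feature_id} has no retention index; RI filter skipped"
        )
    hits = []
    for rec in library:
        mf = match_factor(feature.spectrum, rec.spectrum, **mf_kwargs)
        if mf <= mf_min:
            continue
        rmf = reverse_match_factor(feature.spectrum, rec.spectrum, **mf_kwargs)
        if rmf <= rmf_min:
            continue
        ri_diff = None
        if feature.ri is not None and rec.ri is not None:
            ri_diff = abs(feature.ri - rec.ri)
            if ri_diff >= ri_tol:
                continue
        hits.append(CandidateHit(rec, mf, rmf, ri_diff))
    hits.sort(
        key=lambda h: (
            -(h.mf + h.rmf) / 2.0,
            h.ri_diff if h.ri_diff is not None else float("inf"),
            h.record.structure_id,
        )
    )
    if top_k is not None:
        hits = hits[:top_k]
    for rank, h in enumerate(hits, start=1):
        h.rank = rank
    return hits


# ---------------------------------------------------------------------------
# feature-table filtering and isomer grouping
# ---------------------------------------------------------------------------


def prefilter_features(
    feature_table: pd.DataFrame,
    blank_table: pd.DataFrame,
    min_area: float = 1e5,
    blank_ratio: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove low-abundance and blank-dominated features.

    Both tables index rows by ``feature_id`` and carry ``area_<sample>``
    columns. A feature survives if its maximum sample area reaches
    ``min_area`` and exceeds its maximum blank area by at least
    ``blank_ratio``. Per-filter removal counts are returned for the
    screening-funnel accounting.
    """
    area_cols = [c for c in feature_table.columns if c.startswith("area_")]
    blank_cols = [c for c in blank_table.columns if c.startswith("area_")]
    if not area_cols or "feature_id" not in feature_table.columns:
        raise SchemaError("feature table needs 'feature_id' and 'area_*' columns")
    if "feature_id" not in blank_table.columns or not blank_cols:
        raise SchemaError("blank table needs 'feature_id' and 'area_*' columns")

    n_in = len(feature_table)
    max_area = feature_table[area_cols].max(axis=1)
    keep_area = max_area >= min_area
    after_area = feature_table[keep_area]

    blank_max = blank_table.set_index("feature_id")[blank_cols].max(axis=1)
    bmax = after_area["feature_id"].map(blank_max).fillna(0.0)
    with np.errstate(divide="ignore"):
        ratio = np.where(
            bmax.to_numpy() > 0,
            after_area[area_cols].max(axis=1).to_numpy() / bmax.to_numpy(),
            np.inf,
        )
    keep_blank = ratio >= blank_ratio
    out = after_area[keep_blank].reset_index(drop=True)
    counts = {
        "input": n_in,
        "removed_low_area": int(n_in - len(after_area)),
        "removed_blank": int(len(after_area) - len(out)),
        "retained": len(out),
    }
    return out, counts


def group_isomer_features(
    candidates_by_feature: Mapping[str, Iterable[str]],
    rt_by_feature: Mapping[str, float] | None = None,
    rt_window: float | None = None,
) -> tuple[list[IsomerGroup], list[str]]:
    """Collapse features whose top-candidate structure sets intersect.

    Features sharing at least one candidate structure fall into the same
    connected component; components of size >= 2 become isomer groups,
    singletons remain "unique". When ``rt_window`` is given, only features
    within that RT distance are linked. Grouping is independent of input
    order and conserves the feature count.
    """
    fids = sorted(candidates_by_feature)
    sets = {f: frozenset(candidates_by_feature[f]) for f in fids}
    idx = {f: i for i, f in enumerate(fids)}
    rows, cols = [], []
    for i, fa in enumerate(fids):
        for fb in fids[i + 1 :]:
            if not (sets[fa] & sets[fb]):
                continue
            if rt_window is not None and rt_by_feature is not None:
                if abs(rt_by_feature[fa] - rt_by_feature[fb]) > rt_window:
                    continue
            rows.append(idx[fa])
            cols.append(idx[fb])
    n = len(fids)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    groups, unique = [], []
    for comp in range(n_comp):
        members = [fids[i] for i in range(n) if labels[i] == comp]
        if len(members) == 1:
            unique.append(members[0])
        else:
            shared = sorted(frozenset.union(*(sets[m] for m in members)))
            groups.append(IsomerGroup(sorted(members), shared))
    return groups, sorted(unique)


# ---------------------------------------------------------------------------
# table i/o
# ---------------------------------------------------------------------------


def _spectrum_to_str(spec: MassSpectrum) -> str:
    return " ".join(f"{m:.4f}:{i:.1f}" for m, i in zip(spec.mz, spec.intensity))


def _spectrum_from_str(text: str) -> MassSpectrum:
    mz, inten = [], []
    for tok in text.split():
        m, i = tok.split(":")
        mz.append(float(m))
        inten.append(float(i))
    return MassSpectrum(np.array(mz), np.array(inten))


def write_feature_table(features: Sequence[Feature], path) -> None:
    """Write features as TSV with an embedded ``mz:intensity`` spectrum column."""
    sample_ids = sorted({s for f in features for s in f.area_by_sample})
    rows = []
    for f in features:
        row = {
            "feature_id": f.feature_id,
            "rt": f.rt,
            "model_ion_mz": f.model_ion_mz,
            "ri": f.ri,
            "spectrum": _spectrum_to_str(f.spectrum),
        }
        for s in sample_ids:
            row[f"area_{s}"] = f.area_by_sample.get(s, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> list[Feature]:
    df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "rt", "spectrum"}
    if missing := required - set(df.columns):
        raise SchemaError(f"feature table missing columns {sorted(missing)}")
    area_cols = [c for c in df.columns if c.startswith("area_")]
    features = []
    for _, row in df.iterrows():
        ri = row.get("ri")
        mz = row.get("model_ion_mz")
        features.append(
            Feature(
                feature_id=str(row["feature_id"]),
                rt=float(row["rt"]),
                spectrum=_spectrum_from_str(row["spectrum"]),
                model_ion_mz=None if pd.isna(mz) else float(mz),
                ri=None if pd.isna(ri) else float(ri),
                area_by_sample={c[len("area_") :]: float(row[c]) for c in area_cols},
            )
        )
    return features


def read_alkane_ladder(path) -> AlkaneLadder:
    """Read an alkane ladder CSV with columns ``n`` and ``rt``."""
    df = pd.read_csv(path)
    if missing := {"n", "rt"} - set(df.columns):
        raise SchemaError(f"alkane ladder missing columns {sorted(missing)}")
    return AlkaneLadder(list(zip(df["n"], df["rt"])))
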