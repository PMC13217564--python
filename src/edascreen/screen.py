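"""Virtual fractionation: keep only features whose candidates can explain activity.

Physical effect-directed analysis narrows down causative chemicals by
fractionating an extract and re-testing fractions. Virtual fractionation
replaces that loop in silico: a nontarget feature is discarded when *none*
of its top-ranking library candidates is predicted to be an AhR agonist.
Features are handled at the isomer-group level (features sharing top
candidates cannot be distinguished by EI spectra alone), identification
confidence is communicated on a 3-level scale, and the per-sample
accounting that the screening funnel reports is kept explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .spectra import CandidateHit, Feature, IsomerGroup, MassSpectrum, match_factor

__all__ = [
    "CandidatePrediction",
    "AnnotatedFeature",
    "ScreenSummary",
    "Standard",
    "virtually_fractionate",
    "assign_confidence_level",
    "per_sample_overlap",
]


@dataclass
class CandidatePrediction:
    """A library hit decorated with the QSAR verdicts."""

    hit: CandidateHit
    predicted_active: bool | None = None
    predicted_ec10: float | None = None  # uM
    in_domain: bool = True

    @property
    def structure_id(self) -> str:
        return self.hit.record.structure_id


@dataclass
class AnnotatedFeature:
    """A feature with its candidate predictions, confidence level and evidence."""

    feature: Feature
    candidates: list[CandidatePrediction] = field(default_factory=list)
    cl: int | None = None
    evidence: set[str] = field(default_factory=set)


@dataclass
class ScreenSummary:
    """Funnel accounting of one virtual-fractionation pass."""

    n_features_in: int
    n_unique: int
    n_isomer_groups: int
    n_unique_active: int
    n_groups_active: int

    @property
    def n_retained_total(self) -> int:
        return self.n_unique_active + self.n_groups_active


@dataclass(frozen=True)
class Standard:
    """An authentic reference standard: spectrum plus retention time."""

    name: str
    structure_id: str
    rt: float
    spectrum: MassSpectrum | None = None


def _feature_active(af: AnnotatedFeature) -> bool:
    for cand in af.candidates:
        if cand.predicted_active is None:
            raise ValueError(
                f"candidate {cand.structure_id} of feature "
                f"{af.feature.feature_id} lacks an activity prediction"
            )
    return any(c.predicted_active for c in af.candidates)


def virtually_fractionate(
    annotated_features: Sequence[AnnotatedFeature],
    groups: Sequence[IsomerGroup] = (),
) -> tuple[list[AnnotatedFeature], ScreenSummary]:
    """Drop features none of whose top candidates is predicted active.

    A unique feature is retained iff at least one candidate is predicted
    active; an isomer group is retained iff at least one candidate shared
    by its members is predicted active (then all member features are
    retained together). Returns the retained features and the funnel
    summary. Idempotent: re-screening the retained set changes nothing.
    """
    by_id = {af.feature.feature_id: af for af in annotated_features}
    grouped_ids = {fid for g in groups for fid in g.feature_ids if fid in by_id}
    unique = [af for af in annotated_features if af.feature.feature_id not in grouped_ids]

    retained: list[AnnotatedFeature] = []
    n_unique_active = 0
    for af in unique:
        if _feature_active(af):
            n_unique_active += 1
            retained.append(af)

    n_groups = 0
    n_groups_active = 0
    for g in groups:
        members = [by_id[fid] for fid in g.feature_ids if fid in by_id]
        if not members:
            continue
        n_groups += 1
        if any(_feature_active(m) for m in members):
            n_groups_active += 1
            retained.extend(members)

    summary = ScreenSummary(
        n_features_in=len(annotated_features),
        n_unique=len(unique),
        n_isomer_groups=n_groups,
        n_unique_active=n_unique_active,
        n_groups_active=n_groups_active,
    )
    return retained, summary


def assign_confidence_level(
    annotated: AnnotatedFeature,
    standards: Sequence[Standard],
    mf_min_standard: float = 800.0,
    rt_tol: float = 0.1,
) -> int | None:
    """Assign identification confidence: 1 standard-confirmed, 2 library
    match within RI tolerance, 3 characteristic ions only.

    CL1 requires a spectral match (MF >= ``mf_min_standard``) *and* an RT
    match (|dRT| <= ``rt_tol`` min) against an authentic standard. CL2
    requires a surviving library candidate whose RI difference was within
    tolerance. CL3 is granted only on externally supplied
    ``characteristic_ions_only`` evidence. The level and the evidence set
    are recorded on the feature.
    """
    feat = annotated.feature
    for std in standards:
        if std.spectrum is None:
            continue
        if abs(feat.rt - std.rt) <= rt_tol:
            if match_factor(feat.spectrum, std.spectrum) >= mf_min_standard:
                annotated.evidence |= {"spectrum_match", "rt_standard_match"}
                annotated.cl = 1
                return 1
    if any(c.hit.ri_diff is not None for c in annotated.candidates):
        annotated.evidence |= {"spectrum_match", "ri_within_tol"}
        annotated.cl = 2
        return 2
    if "characteristic_ions_only" in annotated.evidence:
        annotated.cl = 3
        return 3
    annotated.cl = None
    return None


def per_sample_overlap(retained_by_sample: Mapping[str, set[str]]) -> pd.DataFrame:
    """Pairwise intersection counts of retained candidate structures."""
    if len(retained_by_sample) < 2:
        raise ValueError("need at least 2 samples")
    samples = sorted(retained_by_sample)
    mat = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    for a in samples:
        for b in samples:
            mat.loc[a, b] = len(set(retained_by_sample[a]) & set(retained_by_sample[b]))
    return mat
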