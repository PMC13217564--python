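import numpy as np
import pytest

from edascreen.fixtures import gen_world
from edascreen.screen import AnnotatedFeature, CandidatePrediction
from edascreen.spectra import CandidateHit, Feature, IsomerGroup, LibraryRecord, MassSpectrum


@pytest.fixture(scope="session")
def world():
    """One shared synthetic study (seed 7, 30% planted explained fraction)."""
    return gen_world(n_active=30, n_inactive=30, n_samples=3, explained_target=0.3, seed=7)


def _dummy_spectrum() -> MassSpectrum:
    return MassSpectrum(np.array([100.0, 200.0]), np.array([999.0, 500.0]))


def make_annotated(feature_id: str, candidate_ids, active_ids, rt: float = 5.0):
    """An annotated feature whose candidates carry activity predictions."""
    spectrum = _dummy_spectrum()
    feat = Feature(feature_id=feature_id, rt=rt, spectrum=spectrum)
    candidates = []
    for cid in candidate_ids:
        rec = LibraryRecord(name=cid, spectrum=_dummy_spectrum(), inchikey=cid)
        hit = CandidateHit(rec, mf=900.0, rmf=950.0, ri_diff=10.0)
        candidates.append(CandidatePrediction(hit, predicted_active=cid in active_ids))
    return AnnotatedFeature(feature=feat, candidates=candidates)


def build_screen_case(n_unique, n_unique_active, n_groups, n_groups_active, group_size=2):
    """A screening scenario with exact planted funnel counts."""
    features, groups = [], []
    for i in range(n_unique):
        cid = f"U{i:04d}"
        features.append(make_annotated(f"fu{i:04d}", [cid], {cid} if i < n_unique_active else set()))
    for g in range(n_groups):
        cid = f"G{g:04d}"
        members = []
        for m in range(group_size):
            fid = f"fg{g:04d}_{m}"
            members.append(fid)
            features.append(
                make_annotated(fid, [cid], {cid} if g < n_groups_active else set())
            )
        groups.append(IsomerGroup(members, [cid]))
    return features, groups
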