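"""Iceberg modeling: how much of the observed effect do known chemicals explain?

The bioassay measures the whole extract's B[a]P-equivalents (BEQ_bio, the
iceberg); the chemicals actually identified and quantified carry
BEQ_chem = sum REP_i * C_i (the tip). This module builds per-sample
ledgers of chemical contributions, computes the explained fraction and
subset contributions (e.g. the EPA priority PAHs alone), and produces
prioritized rankings with cumulative shares.

Measured relative effect potencies always take precedence over
QSAR-predicted ones, and predicted-REP entries stay distinguishable in
every output so they can be excluded from regulatory-style sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .bioassay import bap_eq_chem, contribution
from .quant import QuantifiedChemical

__all__ = [
    "ChemicalContribution",
    "SampleLedger",
    "build_ledger",
    "top_n_share",
    "subset_contribution",
    "rank_report",
]


@dataclass
class ChemicalContribution:
    """One chemical's entry in a sample ledger: beq = REP x concentration."""

    structure_id: str
    rep: float
    concentration: float  # ug/g_sed,dw; MDL/2 or 0 for censored entries
    rep_source: str  # measured | predicted
    censored: bool = False
    in_domain: bool = True
    tags: frozenset[str] = frozenset()
    method: str | None = None

    def __post_init__(self):
        if self.rep < 0 or self.concentration < 0:
            raise ValueError("REP and concentration must be non-negative")
        if self.rep_source not in {"measured", "predicted"}:
            raise ValueError(f"unknown REP source {self.rep_source!r}")

    @property
    def beq(self) -> float:
        return self.rep * self.concentration


@dataclass
class SampleLedger:
    """Per-sample explained-effect ledger."""

    sample_id: str
    contributions: list[ChemicalContribution]
    beq_bio: float  # ug B[a]P / g_sed,dw
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.beq_bio <= 0:
            raise ValueError("BEQ_bio must be positive")

    @property
    def beq_chem(self) -> float:
        return bap_eq_chem([(c.rep, c.concentration) for c in self.contributions])

    @property
    def explained_fraction(self) -> float:
        """Explained effect in percent of BEQ_bio."""
        return contribution(self.beq_chem, self.beq_bio)


def build_ledger(
    quantified: Sequence[QuantifiedChemical],
    measured_rep: Mapping[str, float],
    beq_bio: float,
    sample_id: str = "",
    predicted_rep: Mapping[str, float] | None = None,
    in_domain: Mapping[str, bool] | None = None,
    tags: Mapping[str, frozenset[str]] | None = None,
    censored_policy: str = "zero",
    measured_only: bool = False,
) -> SampleLedger:
    """Assemble a sample's ledger from quantified chemicals and REPs.

    A chemical's REP is taken from ``measured_rep`` when available,
    otherwise from ``predicted_rep`` (flagged as predicted, with the
    applicability-domain flag carried). ``measured_only=True`` drops
    predicted-REP entries, enforcing the confirmed-chemicals-only view.
    Censored concentrations contribute 0 (default) or MDL/2
    (``censored_policy="half_mdl"``). Chemicals without any REP are
    excluded with a reason.
    """
    predicted_rep = predicted_rep or {}
    contribs: list[ChemicalContribution] = []
    excluded: list[tuple[str, str]] = []
    for q in quantified:
        sid = q.structure_id
        if sid in measured_rep:
            rep_val, source = measured_rep[sid], "measured"
        elif sid in predicted_rep and not measured_only:
            rep_val, source = predicted_rep[sid], "predicted"
        elif sid in predicted_rep:
            excluded.append((sid, "predicted REP only; excluded by measured_only"))
            continue
        else:
            excluded.append((sid, "no measured or predicted REP"))
            continue
        if q.censored:
            if censored_policy == "half_mdl" and q.mdl_per_g is not None:
                conc = q.mdl_per_g / 2.0
            elif censored_policy == "zero":
                conc = 0.0
            else:
                raise ValueError(f"unknown censoring policy {censored_policy!r}")
        else:
            conc = q.concentration
        contribs.append(
            ChemicalContribution(
                structure_id=sid,
                rep=rep_val,
                concentration=conc,
                rep_source=source,
                censored=q.censored,
                in_domain=(in_domain or {}).get(sid, True),
                tags=(tags or {}).get(sid, frozenset()),
                method=q.method,
            )
        )
    return SampleLedger(sample_id or (quantified[0].sample_id if quantified else ""),
                        contribs, beq_bio, excluded)


def top_n_share(ledger: SampleLedger, n: int = 10) -> float:
    """Share (%) of BEQ_chem held by the n largest chemical contributions."""
    if not ledger.contributions:
        raise ValueError("empty ledger")
    beqs = sorted((c.beq for c in ledger.contributions), reverse=True)
    total = sum(beqs)
    if total == 0:
        return 0.0
    return 100.0 * sum(beqs[:n]) / total


def subset_contribution(ledger: SampleLedger, tag: str) -> float:
    """Explained effect (%) attributable to chemicals carrying a subset tag."""
    known_tags = set().union(*(c.tags for c in ledger.contributions), set())
    if tag not in known_tags:
        raise KeyError(f"unknown subset tag {tag!r}")
    tagged = sum(c.beq for c in ledger.contributions if tag in c.tags)
    return contribution(tagged, ledger.beq_bio)


def rank_report(ledger: SampleLedger) -> pd.DataFrame:
    """Prioritized table: descending BEQ with cumulative share of BEQ_chem.

    Ties are broken lexicographically by structure id, making the report
    deterministic.
    """
    rows = sorted(
        ledger.contributions, key=lambda c: (-c.beq, c.structure_id)
    )
    total = sum(c.beq for c in rows)
    out, cum = [], 0.0
    for c in rows:
        cum += c.beq
        out.append(
            {
                "structure_id": c.structure_id,
                "rep": c.rep,
                "rep_source": c.rep_source,
                "concentration": c.concentration,
                "beq": c.beq,
                "share_pct": 100.0 * c.beq / total if total > 0 else 0.0,
                "cumulative_pct": 100.0 * cum / total if total > 0 else 0.0,
                "in_domain": c.in_domain,
                "censored": c.censored,
            }
        )
    return pd.DataFrame(out)
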