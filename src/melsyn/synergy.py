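"""Bliss-independence synergy scoring for two-drug dose matrices.

The Bliss model treats the two drugs as independent "kill" events: the
expected combination cytotoxicity of drugs with single-agent effects
``c_a`` and ``c_b`` is ``1 - (1 - c_a) * (1 - c_b)``.  The synergy score
of an observed combination cell is the observed cytotoxicity minus this
expectation; positive scores indicate synergy, negative antagonism.

Observed cytotoxicity fractions can legitimately fall outside [0, 1]
(negative = net growth under drug).  The Bliss expectation is only
defined for probabilities, so single-agent effects are clamped to [0, 1]
before entering the expectation, while the observed combination value is
used as-is in the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DoseResponsePanel

__all__ = [
    "bliss_expected",
    "bliss_score",
    "synergy_matrix",
    "panel_summary",
    "estimate_ic50",
    "IC50NotReached",
    "SynergyMatrix",
]


def _check_finite(*values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite cytotoxicity value")


def bliss_expected(c_a, c_b):
    """Expected combination cytotoxicity under Bliss independence.

    Inputs are clamped to [0, 1]; the function is symmetric in its
    arguments and broadcasts over arrays.
    """
    _check_finite(c_a, c_b)
    a = np.clip(c_a, 0.0, 1.0)
    b = np.clip(c_b, 0.0, 1.0)
    out = 1.0 - (1.0 - a) * (1.0 - b)
    return float(out) if np.isscalar(c_a) and np.isscalar(c_b) else out


def bliss_score(c_comb, c_a, c_b):
    """Observed combination cytotoxicity minus the Bliss expectation.

    ``c_comb`` enters unclamped: combination kill beyond the single-agent
    bounds is real signal, not a model violation.
    """
    _check_finite(c_comb)
    out = np.asarray(c_comb, dtype=float) - bliss_expected(c_a, c_b)
    return float(out) if np.isscalar(c_comb) else out


@dataclass
class SynergyMatrix:
    """Per-line Bliss excess over the combination dose grid."""

    line: str
    scores: pd.DataFrame  # doses of drug A x doses of drug B
    summary: float  # arithmetic mean over the grid

    @property
    def shape(self):
        return self.scores.shape


def synergy_matrix(panel: DoseResponsePanel, line: str) -> SynergyMatrix:
    """Bliss synergy scores for one cell line over its combination grid.

    Replicate-averaged cytotoxicities are used throughout (the analysis
    operates on averages of cytotoxicity values across replicates).  The
    per-line summary score is the arithmetic mean over all grid cells.
    """
    singles_a = panel.single_means(line, panel.drug_a)
    singles_b = panel.single_means(line, panel.drug_b)
    combo = panel.combo_means(line)
    missing_a = set(combo.index) - set(singles_a.index)
    missing_b = set(combo.columns) - set(singles_b.index)
    if missing_a or missing_b:
        raise ValueError(f"line {line!r}: combination doses without single-drug data")
    if combo.isna().any().any():
        raise ValueError(f"line {line!r}: missing combination dose cell")
    sa = singles_a.loc[combo.index].to_numpy()[:, None]
    sb = singles_b.loc[combo.columns].to_numpy()[None, :]
    scores = bliss_score(combo.to_numpy(), sa, sb)
    scores = pd.DataFrame(scores, index=combo.index, columns=combo.columns)
    return SynergyMatrix(line=line, scores=scores, summary=float(scores.to_numpy().mean()))


def panel_summary(panel: DoseResponsePanel) -> pd.DataFrame:
    """Per-line synergy summary table with descending-rank annotation."""
    rows = []
    for line in panel.lines:
        sm = synergy_matrix(panel, line)
        rows.append({"line": line, "summary_score": sm.summary})
    out = pd.DataFrame(rows).set_index("line")
    out["rank"] = out["summary_score"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("summary_score", ascending=False)


class IC50NotReached(ValueError):
    """Signals that cytotoxicity 0.5 is never bracketed by the dose range."""


def estimate_ic50(doses, cyto) -> float:
    """Concentration producing 50% cytotoxicity by log10-dose interpolation.

    If 0.5 is attained exactly at a measured dose, that dose is returned;
    otherwise the two doses bracketing 0.5 are interpolated linearly in
    log10 concentration.  Raises :class:`IC50NotReached` if the response
    never crosses 0.5.
    """
    doses = np.asarray(doses, dtype=float)
    cyto = np.asarray(cyto, dtype=float)
    if doses.size < 2 or doses.size != cyto.size:
        raise ValueError("need >=2 matched (dose, cytotoxicity) points")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    exact = np.nonzero(cyto == 0.5)[0]
    if exact.size:
        return float(doses[exact[0]])
    for i in range(doses.size - 1):
        lo, hi = cyto[i], cyto[i + 1]
        if (lo - 0.5) * (hi - 0.5) < 0:
            f = (0.5 - lo) / (hi - lo)
            return float(10 ** (np.log10(doses[i]) + f * (np.log10(doses[i + 1]) - np.log10(doses[i]))))
    raise IC50NotReached("cytotoxicity 0.5 not reached within the dose range")
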