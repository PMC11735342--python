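"""Contribution-to-variance sensitivity analysis.

Attributes the variance of a simulated output (e.g. the hazard index) to
its input variables by the convention popularized by spreadsheet
Monte-Carlo tools: for each input, compute the rank (Spearman) correlation
with the output, square it, normalize the squares across inputs to sum to
100%, and carry the correlation's sign.  This is a first-order measure —
interactions are not decomposed — and, being rank-based, it is invariant
under strictly monotone transforms of any input.

A Pearson-based variant is selectable for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["SensitivityResult", "contribution_to_variance"]


@dataclass(frozen=True)
class SensitivityResult:
    """Signed percentage contributions, plus the |contribution| ranking."""

    contributions: dict[str, float]
    ranking: list[str]
    method: str

    def to_frame(self) -> pd.DataFrame:
        """Tornado-style table: one row per input, ordered by |contribution|."""
        return pd.DataFrame(
            {"input": self.ranking, "contribution_percent": [self.contributions[k] for k in self.ranking]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def contribution_to_variance(
    inputs: dict[str, np.ndarray],
    output: np.ndarray,
    method: str = "spearman",
) -> SensitivityResult:
    """Normalized signed squared correlation of each input with the output.

    All vectors must be aligned (drawn jointly) and of equal length >= 10.
    A constant input cannot correlate with anything: it contributes 0% and
    a warning is emitted.
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown method {method!r}")
    if not inputs:
        raise ValidationError("need at least one input vector")
    out = np.asarray(output, dtype=float)
    n = out.size
    if n < 10:
        raise ValidationError(f"need >= 10 joint draws, got {n}")

    corrs: dict[str, float] = {}
    for name, vec in inputs.items():
        v = np.asarray(vec, dtype=float)
        if v.size != n:
            raise ValidationError(f"input {name!r} has length {v.size}, expected {n}")
        if np.all(v == v[0]):
            warnings.warn(f"input {name!r} is constant; its contribution is 0", UserWarning, stacklevel=2)
            corrs[name] = 0.0
            continue
        if method == "spearman":
            r = stats.spearmanr(v, out).statistic
        else:
            r = stats.pearsonr(v, out).statistic
        corrs[name] = 0.0 if np.isnan(r) else float(r)

    total = sum(r**2 for r in corrs.values())
    if total == 0:
        contributions = {k: 0.0 for k in corrs}
    else:
        contributions = {k: float(np.sign(r) * 100.0 * r**2 / total) for k, r in corrs.items()}
    ranking = sorted(contributions, key=lambda k: abs(contributions[k]), reverse=True)
    return SensitivityResult(contributions=contributions, ranking=ranking, method=method)
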