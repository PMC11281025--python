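"""Contribution-to-variance sensitivity analysis of the risk outputs.

Ranks the drivers of THI and TCR from a Monte Carlo draw matrix using the
signed, normalized squared Spearman rank correlation,

    contribution_k = sign(ρ_k) · 100 · ρ_k² / Σ_j ρ_j²,

the "contribution to variance" statistic popularised by spreadsheet risk
tools.  Rank correlation makes the measure invariant under any strictly
monotone transform of an input, which suits the multiplicative dose
equations.  Inputs are the per-metal concentration draws plus the sampled
exposure parameters (IR, EF, BW); body weight sits in the denominator of
the dose equations, so its contribution is expected to be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mc import MCResult

__all__ = ["rank_correlation", "contributions", "SensitivityResult", "analyze_mc"]


def rank_correlation(x, y) -> float:
    """Spearman rank correlation in [-1, 1], with average ranks for ties.

    A zero-variance input has no defined correlation; it is reported as
    0.0 with a warning so that constant inputs drop out of the ranking
    rather than aborting it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("rank_correlation requires two equal-length vectors of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance input: rank correlation undefined, reported as 0",
                      stacklevel=2)
        return 0.0
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class SensitivityResult:
    """Signed contribution-to-variance ranking for one output."""

    output: str
    population: str
    group: str
    contributions: dict[str, float]  # signed %, |values| sum to 100
    correlations: dict[str, float]  # raw Spearman rho per input
    method: str = "spearman-contribution-to-variance"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "output": self.output,
                "population": self.population,
                "group": self.group,
                "input": k,
                "contribution_pct": self.contributions[k],
                "rank_correlation": self.correlations[k],
            }
            for k in self.contributions
        ]
        return pd.DataFrame(rows)

    def ranked(self) -> list[tuple[str, float]]:
        """Inputs sorted by |contribution|, largest first."""
        return sorted(self.contributions.items(), key=lambda kv: -abs(kv[1]))


def contributions(
    inputs: pd.DataFrame,
    output: np.ndarray | pd.Series,
    output_name: str = "output",
    population: str = "",
    group: str = "",
) -> SensitivityResult:
    """Signed contribution-to-variance of each input column to the output.

    Raises if every input is uncorrelated with the output (an output
    insensitive to all inputs has no meaningful ranking).
    """
    if inputs.shape[1] < 2:
        raise ValueError("contributions requires at least 2 input columns")
    y = np.asarray(output, dtype=float)
    rhos = {col: rank_correlation(inputs[col].to_numpy(), y) for col in inputs.columns}
    denom = sum(r * r for r in rhos.values())
    if denom == 0:
        raise ValueError("output insensitive to all inputs: all rank correlations are zero")
    contrib = {k: float(np.sign(r)) * 100.0 * r * r / denom for k, r in rhos.items()}
    return SensitivityResult(
        output=output_name,
        population=population,
        group=group,
        contributions=contrib,
        correlations=rhos,
    )


def analyze_mc(result: MCResult, output: str = "TCR") -> list[SensitivityResult]:
    """Sensitivity of ``output`` ("THI" or "TCR") for every (population, group).

    Concentration inputs are restricted to the metals actually entering
    the output (those with an ``HQ_``/``CR_`` column), alongside the
    sampled exposure parameters IR, EF and BW.
    """
    if output not in ("THI", "TCR"):
        raise ValueError(f"output must be 'THI' or 'TCR', got {output!r}")
    prefix = "HQ_" if output == "THI" else "CR_"
    out = []
    for (pop, group), df in result.frames.items():
        if output not in df.columns:
            continue
        metals = [c.removeprefix(prefix) for c in df.columns if c.startswith(prefix)]
        cols = [f"conc_{m}" for m in metals if f"conc_{m}" in df.columns]
        cols += [c for c in ("IR", "EF", "BW") if df[c].std() > 0]
        inputs = df[cols].rename(columns=lambda c: c.removeprefix("conc_"))
        out.append(
            contributions(inputs, df[output], output_name=output, population=pop, group=group)
        )
    return out
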