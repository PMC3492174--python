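"""Approximately-unbiased (AU) topology test via multiscale RELL bootstrap.

Per-site log-likelihoods are resampled (no refitting) at several scale
factors r; for each candidate topology the bootstrap proportion BP(r) of
replicates it wins is recorded.  Fitting

    Phi^-1(1 - BP(r)) = d*sqrt(r) + c/sqrt(r)

by weighted least squares across scales separates the signed distance d
from the curvature c of the boundary between the best and the candidate
hypothesis regions; the AU p-value is 1 - Phi(d - c).  Topologies with
p below the significance level are rejected as significantly worse than
the maximum-likelihood topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .phylolik import SiteLikelihoodMatrix

__all__ = ["AUResult", "rell_resample", "au_pvalues", "DEFAULT_SCALES"]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))


def _as_matrix(lls) -> tuple[np.ndarray, list[str]]:
    if isinstance(lls, SiteLikelihoodMatrix):
        return lls.values, lls.hypothesis_names
    if isinstance(lls, pd.DataFrame):
        return lls.to_numpy(float), list(lls.columns)
    arr = np.asarray(lls, float)
    return arr, [f"h{i + 1}" for i in range(arr.shape[1])]


def rell_resample(lls, scale: float = 1.0, B: int = 10000,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """Win proportions per hypothesis over B resamples of round(scale*n)
    sites with replacement (ties broken uniformly at random)."""
    values, _names = _as_matrix(lls)
    if scale <= 0:
        raise ValueError("scale must be positive")
    n, h = values.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = max(int(round(scale * n)), 1)
    wins = np.zeros(h)
    p = np.full(n, 1.0 / n)
    # chunk replicates so the count matrix stays small at large n
    chunk = max(1, min(B, int(2e7 // max(n, 1))))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        counts = rng.multinomial(m, p, size=b)
        sums = counts @ values  # (b, h)
        best = sums.max(axis=1, keepdims=True)
        is_max = sums >= best - 1e-9 * np.abs(best)
        winners = sums.argmax(axis=1)
        for i in np.where(is_max.sum(axis=1) > 1)[0]:
            winners[i] = rng.choice(np.where(is_max[i])[0])
        wins += np.bincount(winners, minlength=h)
        done += b
    return wins / B


@dataclass
class AUResult:
    """Per-hypothesis AU p-values with the underlying bootstrap table."""

    table: pd.DataFrame          # name, loglik, delta, au_pvalue, best, degenerate
    bp: pd.DataFrame             # scales x hypotheses bootstrap proportions
    scales: tuple
    B: int
    seed: int

    @property
    def pvalues(self) -> pd.Series:
        return self.table.set_index("hypothesis")["au_pvalue"]

    @property
    def best(self) -> str:
        return self.table.loc[self.table["best"], "hypothesis"].iloc[0]

    def indistinguishable(self, alpha: float = 0.05) -> list[str]:
        """Hypotheses not significantly worse than the best tree."""
        keep = self.table["best"] | (self.table["au_pvalue"] > alpha)
        return list(self.table.loc[keep, "hypothesis"])

    def summary(self) -> str:
        lines = [f"AU test ({self.B} replicates x scales "
                 f"{', '.join(str(s) for s in self.scales)})"]
        for _, row in self.table.iterrows():
            mark = "*" if row["best"] else (
                " " if row["au_pvalue"] > 0.05 else "x"
            )
            lines.append(
                f"  {mark} {row['hypothesis']:<24s} logL {row['loglik']:14.3f} "
                f"dlogL {row['delta']:10.3f}  p(AU) {row['au_pvalue']:.4f}"
            )
        lines.append("  (* best tree; x rejected at 0.05)")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def au_pvalues(lls, scales=DEFAULT_SCALES, B: int = 10000,
               seed: int = 0) -> AUResult:
    """AU test from a per-site log-likelihood matrix.

    Bootstrap proportions of 0 or 1 get a 0.5/B continuity correction; a
    hypothesis with fewer than two informative scales is flagged degenerate
    and given p = 0 (never wins) or 1 (always wins).
    """
    values, names = _as_matrix(lls)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 hypotheses")
    rng = np.random.default_rng(seed)
    bp = np.stack([rell_resample(values, r, B, rng) for r in scales])
    totals = values.sum(axis=0)
    best_idx = int(totals.argmax())
    rows = []
    sq = np.sqrt(np.asarray(scales, float))
    for j, name in enumerate(names):
        raw = bp[:, j]
        degenerate_scales = (raw <= 0.0) | (raw >= 1.0)
        informative = ~degenerate_scales
        p_j = np.clip(raw, 0.5 / B, 1 - 0.5 / B)
        flag = informative.sum() < 2
        if flag:
            p_au = 1.0 if raw.mean() > 0.5 else 0.0
        else:
            z = norm.ppf(1.0 - p_j)
            # delta-method weights: var(z) = bp(1-bp) / (B * phi(z)^2)
            w = B * norm.pdf(z) ** 2 / (p_j * (1 - p_j))
            X = np.column_stack([sq, 1.0 / sq])
            wx = X * w[:, None]
            beta = np.linalg.solve(X.T @ wx, wx.T @ z)
            d_hat, c_hat = beta
            p_au = float(1.0 - norm.cdf(d_hat - c_hat))
        rows.append(
            {
                "hypothesis": name,
                "loglik": float(totals[j]),
                "delta": float(totals[best_idx] - totals[j]),
                "au_pvalue": float(p_au),
                "best": j == best_idx,
                "degenerate": bool(flag),
            }
        )
    table = pd.DataFrame(rows)
    bp_df = pd.DataFrame(bp, index=list(scales), columns=names)
    return AUResult(table, bp_df, tuple(scales), B, seed)
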