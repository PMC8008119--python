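"""Sloan neutral community model for the occupancy-abundance relationship.

An OTU with mean metacommunity relative abundance p is detected in a local
community of N individuals with probability

    occupancy(p; m, N) = 1 - B(d; N*m*p, N*m*(1-p)),   d = 1/N,

where B is the regularized incomplete-beta CDF and d the detection limit of
one read. The migration rate m (probability that a death is replaced by an
immigrant rather than local reproduction) is the single free parameter; a
lower m means stronger dispersal limitation in community turnover.

Fitting follows the familiar occupancy-frequency procedure: p_i is the mean
relative abundance of OTU i across samples, freq_i the fraction of samples
in which it occurs, m is estimated by bounded least squares of freq against
the predicted occupancy, and R^2 = 1 - SS_res/SS_tot is computed on the
untransformed frequencies (the log transform of abundance is for plotting
only). OTUs are classed above/within/below a 95% binomial confidence band
(Wilson by default) around the prediction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.stats.proportion import proportion_confint

from .core import OtuTable
from .errors import NotRarefiedError

M_BOUNDS = (1e-6, 1.0)


def predict_occupancy(p, m: float, N: int):
    """Expected occurrence frequency of an OTU with mean relative abundance p."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("relative abundance p must lie in (0, 1)")
    if not (0 < m <= 1):
        raise ValueError("migration rate m must lie in (0, 1]")
    if N < 1:
        raise ValueError("community size N must be >= 1")
    d = 1.0 / N
    a = N * m * p
    b = N * m * (1.0 - p)
    out = 1.0 - special.betainc(a, b, d)
    return float(out) if out.ndim == 0 else out


class SloanNeutralModel:
    """Neutral-model fit of occupancy vs mean relative abundance.

    Parameters
    ----------
    table
        Rarefied OTU table (equal row sums); the common depth is N.
    force
        Accept unequal row sums (N set to the rounded mean depth).
    """

    def __init__(self, table: OtuTable, force: bool = False):
        sums = table.sample_sums()
        if sums.nunique() > 1 and not force:
            raise NotRarefiedError(
                "sample depths are unequal; rarefy first (or pass force=True)"
            )
        if table.n_otus < 10 or table.n_samples < 5:
            raise ValueError("neutral fit needs >= 10 OTUs and >= 5 samples")
        self.table = table
        self.N = int(round(sums.mean()))
        counts = table.counts.astype(float)
        rel = counts / counts.sum(axis=1, keepdims=True)
        self.p = rel.mean(axis=0)
        self.freq = (counts > 0).mean(axis=0)
        self.n_samples = table.n_samples

    def _loss(self, m: float) -> float:
        pred = predict_occupancy(self.p, m, self.N)
        return float(np.sum((self.freq - pred) ** 2))

    def fit(self, ci_method: str = "wilson", xatol: float = 1e-8) -> "SloanNeutralResults":
        res = optimize.minimize_scalar(
            self._loss, bounds=M_BOUNDS, method="bounded", options={"xatol": xatol}
        )
        m = float(res.x)
        pred = predict_occupancy(self.p, m, self.N)
        ss_res = np.sum((self.freq - pred) ** 2)
        ss_tot = np.sum((self.freq - self.freq.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot
        if ci_method == "wilson":
            lower, upper = proportion_confint(
                pred * self.n_samples, self.n_samples, alpha=0.05, method="wilson"
            )
        elif ci_method == "normal":
            se = np.sqrt(pred * (1 - pred) / self.n_samples)
            lower, upper = np.clip(pred - 1.96 * se, 0, 1), np.clip(pred + 1.96 * se, 0, 1)
        else:
            raise ValueError("ci_method must be 'wilson' or 'normal'")
        cls = np.where(self.freq > upper, "above", np.where(self.freq < lower, "below", "within"))
        per_otu = pd.DataFrame(
            {
                "mean_relative_abundance": self.p,
                "occupancy_observed": self.freq,
                "occupancy_predicted": pred,
                "ci_lower": lower,
                "ci_upper": upper,
                "otu_class": cls,
            },
            index=self.table.otu_ids,
        )
        return SloanNeutralResults(self, m, r2, per_otu, ci_method)


class SloanNeutralResults:
    """Fitted migration rate, fit quality and per-OTU classification."""

    def __init__(self, model, m, r2, per_otu, ci_method):
        self.model = model
        self.m = m
        self.rsquared = r2
        self.per_otu = per_otu
        self.ci_method = ci_method
        self.N = model.N
        self.detection_limit = 1.0 / model.N

    def classify_otus(self) -> dict[str, int]:
        """Counts per above/within/below class (sums to the OTU count)."""
        counts = self.per_otu["otu_class"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("above", "within", "below")}

    def interpretation(self) -> str:
        return (
            f"m = {self.m:.4g}: a lower value of m suggests more limited "
            "dispersal in the turnover of the community."
        )

    def summary(self) -> str:
        cls = self.classify_otus()
        lines = [
            "Sloan neutral community model",
            "=============================",
            f"samples:            {self.model.n_samples}",
            f"OTUs:               {len(self.per_otu)}",
            f"community size N:   {self.N}",
            f"detection limit d:  {self.detection_limit:.6g}",
            f"migration rate m:   {self.m:.6g}",
            f"R-squared:          {self.rsquared:.4f}",
            f"OTUs above band:    {cls['above']}",
            f"OTUs within band:   {cls['within']}  ({self.ci_method} 95% CI)",
            f"OTUs below band:    {cls['below']}",
            self.interpretation(),
        ]
        return "\n".join(lines)

    def bootstrap_m_ci(self, n_boot: int = 200, seed: int = 0, alpha: float = 0.05):
        """Bootstrap-over-OTUs percentile CI for m (reporting extension)."""
        rng = np.random.default_rng(seed)
        n = len(self.model.p)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            p, freq = self.model.p[idx], self.model.freq[idx]

            def loss(m):
                return float(np.sum((freq - predict_occupancy(p, m, self.N)) ** 2))

            draws[b] = optimize.minimize_scalar(
                loss, bounds=M_BOUNDS, method="bounded", options={"xatol": 1e-6}
            ).x
        return tuple(np.quantile(draws, [alpha / 2, 1 - alpha / 2]))

    def plot(self, ax=None):
        """Occupancy vs log10 mean relative abundance with the 95% band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.per_otu.sort_values("mean_relative_abundance")
        x = np.log10(t["mean_relative_abundance"])
        colors = t["otu_class"].map(
            {"above": "tab:cyan", "within": "0.3", "below": "tab:red"}
        )
        ax.scatter(x, t["occupancy_observed"], s=12, c=colors)
        ax.plot(x, t["occupancy_predicted"], color="tab:blue")
        ax.plot(x, t["ci_lower"], "--", color="tab:blue", lw=0.8)
        ax.plot(x, t["ci_upper"], "--", color="tab:blue", lw=0.8)
        ax.set_xlabel("log10 mean relative abundance")
        ax.set_ylabel("occurrence frequency")
        ax.set_title(f"Sloan neutral model (m={self.m:.3g}, R2={self.rsquared:.3f})")
        return ax


def fit_sloan(table: OtuTable, force: bool = False, ci_method: str = "wilson"):
    """Convenience wrapper: build the model and fit it."""
    return SloanNeutralModel(table, force=force).fit(ci_method=ci_method)
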