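"""Figure helpers: fitted TPC with credible band, plus point-and-interval
panels contrasting individual and aggregated fits."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # file output only; no display backend assumed
import matplotlib.pyplot as plt  # noqa: E402

from .tpc import PosteriorSummary, TPCChain, briere


def plot_fit(data, chain: TPCChain, path, n_curve: int = 300,
             n_draws: int = 400, title: str | None = None) -> None:
    """Scatter the observations and draw the posterior median curve with a
    95% credible band for the central response."""
    t_obs = np.array([p[0] for p in data])
    y_obs = np.array([p[1] for p in data])
    lo = min(chain.get("t_min").min(), t_obs.min()) - 1.0
    hi = max(chain.get("t_max").max(), t_obs.max()) + 1.0
    grid = np.linspace(lo, hi, n_curve)

    idx = np.linspace(0, chain.samples.shape[0] - 1, n_draws).astype(int)
    curves = np.stack([
        briere(grid, chain.samples[i, 0], chain.samples[i, 1], chain.samples[i, 2])
        for i in idx
    ])
    med = np.median(curves, axis=0)
    band_lo, band_hi = np.percentile(curves, [2.5, 97.5], axis=0)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(grid, band_lo, band_hi, alpha=0.3, label="95% credible band")
    ax.plot(grid, med, lw=2, label="posterior median curve")
    ax.plot(t_obs, y_obs, "o", ms=4, alpha=0.6, label="observations")
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel("trait value")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_comparison(fit_individual: PosteriorSummary,
                    fit_aggregated: PosteriorSummary, path) -> None:
    """Point-and-interval panels for T_pk, T_min, and T_max from both fits."""
    panels = ("t_pk", "t_min", "t_max")
    fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3.5),
                             sharey=False)
    for ax, name in zip(axes, panels):
        for x, (label, summary, marker) in enumerate(
            (("individual", fit_individual, "D"),
             ("aggregated", fit_aggregated, "^"))
        ):
            s = summary.params[name]
            ax.errorbar([x], [s.median],
                        yerr=[[s.median - s.hpd_low], [s.hpd_high - s.median]],
                        fmt=marker, capsize=4, ms=7, label=label)
        ax.set_xticks([0, 1], ["individual", "aggregated"])
        ax.set_xlim(-0.5, 1.5)
        ax.set_title(name)
        ax.set_ylabel("degC" if name != "peak_rate" else "trait units")
    fig.suptitle("median and 95% HPD by data representation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
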