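"""Diagnostic plots: dose-response, Lineweaver-Burk, Dixon, Kobs line."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def dose_response_plot(concentrations, inhibitions, result, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    c = np.asarray(concentrations, dtype=float)
    ax.semilogx(c, inhibitions, "o", color="k", ms=4)
    grid = np.logspace(np.log10(c[c > 0].min()) - 0.5, np.log10(c.max()) + 0.5, 200)
    curve = grid**result.hill / (grid**result.hill + result.ic50**result.hill)
    ax.semilogx(grid, curve, "-", color="tab:blue")
    ax.axvline(result.ic50, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("inhibitor (µM)")
    ax.set_ylabel("fractional inhibition")
    ax.set_title(f"IC50 = {result.ic50:.3g} µM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def lineweaver_burk_plot(grid, lb_result, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for i_level, line in sorted(lb_result.lines.items()):
        sel = grid.inhibitor == i_level
        x = 1.0 / grid.substrate[sel]
        ax.plot(x, 1.0 / grid.velocity[sel], "o", ms=4)
        xs = np.linspace(min(0, x.min()) * 1.2, x.max() * 1.1, 50)
        ax.plot(xs, line.slope * xs + line.y_intercept, "-", lw=0.9,
                label=f"[I]={i_level:g} µM")
    ax.axhline(0, color="k", lw=0.6)
    ax.axvline(0, color="k", lw=0.6)
    ax.set_xlabel("1/[S] (µM$^{-1}$)")
    ax.set_ylabel("1/v (min/RFU)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dixon_plot(grid, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for s_level in np.unique(grid.substrate):
        sel = grid.substrate == s_level
        order = np.argsort(grid.inhibitor[sel])
        ax.plot(
            grid.inhibitor[sel][order],
            1.0 / grid.velocity[sel][order],
            "o-",
            ms=4,
            label=f"[S]={s_level:g} µM",
        )
    ax.axhline(0, color="k", lw=0.6)
    ax.set_xlabel("[I] (µM)")
    ax.set_ylabel("1/v (min/RFU)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def kobs_plot(result, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    tab = result.kobs_per_inhibitor
    ax.plot(tab["inhibitor_uM"], tab["kobs"], "o", color="k", ms=4)
    xs = np.linspace(0, tab["inhibitor_uM"].max() * 1.1, 50)
    ax.plot(xs, result.k4 + result.k3 * xs, "-", color="tab:blue")
    ax.set_xlabel("[I] (µM)")
    ax.set_ylabel("K$_{obs}$ (min$^{-1}$)")
    ax.set_title(f"k3={result.k3:.4g} µM⁻¹min⁻¹, k4={result.k4:.4g} min⁻¹")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stern_volmer_plot(titration, fit, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    y = titration.f0 / titration.f - 1.0
    ax.plot(titration.quencher, y, "o", color="k", ms=4)
    xs = np.linspace(0, titration.quencher.max() * 1.1, 50)
    ax.plot(xs, fit.ksv * xs, "-", color="tab:blue")
    ax.set_xlabel("[Q] (µM)")
    ax.set_ylabel("F$_0$/F − 1")
    ax.set_title(f"K$_{{SV}}$ = {fit.ksv:.4g} µM⁻¹")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
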