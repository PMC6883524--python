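"""Basic plot exports: coefficient profiles, selection scatter, envelopes
and SWP curves.  Deliberately minimal styling; these mirror the standard
presentation of quantile-coefficient paths and depth contours."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_coefficient_profiles",
    "plot_selection",
    "plot_envelopes",
    "plot_swp_curve",
    "export_all",
]


def plot_coefficient_profiles(profiles, path, ncols: int = 3) -> None:
    n = len(profiles)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 2.8 * nrows), squeeze=False)
    for ax, pr in zip(axes.ravel(), profiles):
        ax.fill_between(pr.quantiles, pr.ci_lower, pr.ci_upper, color="0.8")
        ax.plot(pr.quantiles, pr.estimate, "k.-")
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_title(pr.covariate, fontsize=9)
        ax.set_xlabel("quantile level")
    for ax in axes.ravel()[n:]:
        ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_selection(selection, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"top": "tab:green", "tolerant_only": "tab:blue", "other": "0.6"}
    for cat, sub in selection.groupby("category"):
        ax.scatter(sub["y_c"], sub["y_s"], s=12, c=colors.get(cat, "0.6"), label=cat)
    slope = selection.attrs.get("conditional_slope")
    if slope is not None:
        xx = np.linspace(0, selection["y_c"].max(), 50)
        ax.plot(xx, slope * xx, "b--", lw=1)
    thr = selection.attrs.get("marginal_threshold")
    if thr is not None:
        ax.axhline(thr, color="b", lw=1)
    ax.set_xlabel("non-saline yield (g/m$^2$)")
    ax.set_ylabel("saline yield (g/m$^2$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_envelopes(envelopes, points, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(points[:, 0], points[:, 1], s=8, c="0.7")
    for p, env in sorted(envelopes.items()):
        if env.is_empty or len(env.vertices) == 0:
            continue
        v = np.vstack([env.vertices, env.vertices[:1]])
        ax.plot(v[:, 0], v[:, 1], label=f"p={p:.3g}")
    ax.set_xlabel("saline yield (g/m$^2$)")
    ax.set_ylabel("non-saline yield (g/m$^2$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_swp_curve(curve, path, scatter=None) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 4))
    if scatter is not None:
        ax.scatter(scatter[0], scatter[1], s=8, c="0.8")
    ax.plot(curve["x"], curve["swp_hat"], "k-", label="bivariate prediction")
    ax.plot(curve["x"], curve["band_lower"], "k--", lw=1)
    ax.plot(curve["x"], curve["band_upper"], "k--", lw=1)
    ax.set_xlabel("covariate")
    ax.set_ylabel("SWP (g$^{1/2}$/m)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_all(results: dict, outdir) -> None:
    outdir = Path(outdir)
    if "uqr" in results:
        plot_coefficient_profiles(results["uqr"], outdir / "yield_profiles.png")
    if "swp" in results:
        plot_coefficient_profiles(results["swp"][0], outdir / "swp_profiles.png")
    if "select" in results:
        plot_selection(results["select"], outdir / "selection.png")
    if "envelope" in results and "swp_table" in results:
        envs, _ = results["envelope"]
        pts = results["swp_table"][["y_s", "y_c"]].to_numpy()
        plot_envelopes(envs, pts, outdir / "envelopes.png")
    if "bivreg" in results:
        _, curve = results["bivreg"]
        plot_swp_curve(curve, outdir / "swp_curve.png")
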