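"""Optional PNG rendering of experiment tables (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_phase_cloud", "plot_pulse_drift"]

_STABILITY_COLORS = {"attractor": "black", "repeller": "tab:orange",
                     "saddle": "tab:orange", "center-manifold": "tab:green",
                     "undetermined": "tab:green"}


def plot_phase_cloud(tables: dict, rule: str, alpha: float, path: str,
                     setting: str = "action") -> None:
    """Render one phase-portrait panel: cloud, averaged path, equilibria.

    Boundary accumulation points (clipping artifacts, not zeros of the
    field) are drawn with open markers.
    """
    xcol, ycol = ("w1", "w2") if setting == "action" else ("w", "p")
    cloud = tables["cloud"]
    cloud = cloud[(cloud["rule"] == rule) & (cloud["alpha"] == alpha)]
    apath = tables["averaged_path"]
    apath = apath[(apath["rule"] == rule) & (apath["alpha"] == alpha)]
    eqs = tables["equilibria"]
    eqs = eqs[(eqs["rule"] == rule) & (eqs["alpha"] == alpha)]

    fig, ax = plt.subplots(figsize=(4.2, 4.0))
    cx = cloud["w1"]
    cy = cloud["w2"] if setting == "action" else cloud["p"]
    sc = ax.scatter(cx, cy, c=cloud["step"], s=4, cmap="viridis", alpha=0.5)
    fig.colorbar(sc, ax=ax, label="step")
    ax.plot(apath[xcol], apath[ycol], color="gray", lw=2,
            label="averaged flow")
    for _, row in eqs.iterrows():
        color = _STABILITY_COLORS.get(row["stability"], "tab:green")
        filled = row["kind"] != "boundary-clipped"
        ax.plot(row[xcol], row[ycol], "o", ms=9, mec=color,
                mfc=color if filled else "none", mew=1.8)
    ax.set(xlim=(-0.03, 1.03), ylim=(-0.03, 1.03), xlabel=xcol, ylabel=ycol,
           title=f"{rule}, alpha={alpha:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pulse_drift(drift_table, rule: str, path: str) -> None:
    """E[dw] vs initial weight with the averaged prediction overlaid."""
    cur = drift_table[drift_table["rule"] == rule]
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for key, grp in cur.groupby(["T_del", "epsilon"]):
        label = f"T_del={key[0]:g}s, eps={key[1] * 1000:g}ms"
        ax.errorbar(grp["w_init"], grp["dw_mean"], yerr=grp["dw_sd"],
                    fmt="o", ms=3, capsize=2, label=label)
        ax.plot(grp["w_init"], grp["dw_pred"], "-", lw=1)
    ax.axhline(0.0, color="gray", lw=0.6)
    ax.set(xlabel="initial weight", ylabel="E[dw] per pulse", title=rule)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
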