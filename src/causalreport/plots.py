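"""Optional PNG rendering of the diagnostic plot data.

Rendering is cosmetic: the contract lives in the JSON-serializable plot
data (see diagnostics). These helpers exist so the CLI can drop the
conventional positivity and balance figures next to the report.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .report import CausalReport


def save_overlap_plot(report: CausalReport, path) -> None:
    """Mirrored histograms + densities of the propensity score per arm."""
    ov = report.overlap
    fig, ax = plt.subplots(figsize=(7, 4))
    centers = (ov.bin_edges[:-1] + ov.bin_edges[1:]) / 2.0
    width = ov.bin_edges[1] - ov.bin_edges[0]
    for level, counts in ov.counts.items():
        ax.bar(
            centers,
            counts,
            width=width * 0.9,
            alpha=0.45,
            label=f"{report.exposure_name} = {level}",
        )
        dens = ov.densities.get(level)
        if dens is not None:
            # scale density to count units for a shared axis
            ax.plot(ov.density_grid, dens * counts.sum() * width, lw=1.5)
    ax.set_xlabel(f"Propensity score  P({report.exposure_name}"
                  f"={report.exposure_level} | covariates)")
    ax.set_ylabel("Units")
    ax.set_title("Propensity score overlap by exposure arm")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_balance_plot(report: CausalReport, path, threshold: float = 0.1) -> None:
    """Dot chart of |SMD| per covariate, raw vs IPT-weighted."""
    bal = report.balance
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.4 * len(bal) + 1.5)))
    ypos = range(len(bal))
    ax.scatter(bal["smd_raw"].abs(), ypos, label="unweighted", zorder=3)
    ax.scatter(
        bal["smd_weighted"].abs(), ypos, marker="x", label="IPT-weighted", zorder=3
    )
    ax.axvline(threshold, color="grey", ls="--", lw=1)
    ax.set_yticks(list(ypos))
    ax.set_yticklabels(bal["covariate"])
    ax.invert_yaxis()
    ax.set_xlabel("|standardized mean difference|")
    ax.set_title("Covariate balance before and after weighting")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
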