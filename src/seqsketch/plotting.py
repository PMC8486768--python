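"""Figure rendering and the run-output bundle.

Every plotting run delivers the same bundle the command-line tool promises:
the figure (PDF), the data table (TSV, the canonical artifact), a small R
script that redraws the figure from the TSV, and a run summary.  The TSV is
written at full precision; figures are presentation only.
"""

from __future__ import annotations

import sys
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .aggregate import MetaProfile
from .annotate import FeatureDistribution, SpieData


def _agg_backend():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def write_metaprofile_tsv(mp: MetaProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tmean\n")
        for pos, mean in zip(mp.positions, mp.mean_signal):
            fh.write(f"{pos:g}\t{mean!r}\n")


def read_metaprofile_tsv(path: str | Path) -> MetaProfile:
    positions: list[float] = []
    means: list[float] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            p, m = line.split("\t")
            positions.append(float(p))
            means.append(float(m))
    return MetaProfile(np.array(positions), np.array(means), n_anchors=0)


def plot_metaprofile(
    mp: MetaProfile,
    path: str | Path,
    title: str = "",
    color: str = "#00389c",
    xlabel: str | None = None,
) -> None:
    plt = _agg_backend()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(mp.positions, mp.mean_signal, color=color, lw=1.2)
    ax.axhline(0.0, color="0.8", lw=0.5)
    if xlabel is None:
        xlabel = {
            "TSS": "distance to TSS (bp)",
            "TES": "distance to TES (bp)",
            "PEAK_CENTER": "distance to peak center (bp)",
            "GENE_BODY": "scaled gene body",
        }.get(mp.kind, "position")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("mean normalized signal")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def metaprofile_r_script(tsv_name: str, pdf_name: str, title: str = "") -> str:
    """R script text that redraws the aggregate plot from its TSV."""
    return (
        f'd <- read.delim("{tsv_name}")\n'
        f'pdf("{pdf_name}", width=5, height=3.5)\n'
        f'plot(d$position, d$mean, type="l", col="blue",\n'
        f'     xlab="position", ylab="mean normalized signal", main="{title}")\n'
        "abline(h=0, col=\"grey\")\n"
        "dev.off()\n"
    )


def plot_distribution_pie(
    dist: FeatureDistribution, path: str | Path, title: str = ""
) -> None:
    plt = _agg_backend()
    cats = [c for c, n in dist.counts.items() if n > 0]
    sizes = [dist.counts[c] for c in cats]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.pie(sizes, labels=cats, autopct="%1.1f%%", textprops={"fontsize": 8})
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_spie(spie: SpieData, path: str | Path, title: str = "") -> None:
    """Spie chart: sector angles from the reference, radii sqrt(p_obs/p_ref)."""
    plt = _agg_backend()
    fig = plt.figure(figsize=(4.5, 4.5))
    ax = fig.add_subplot(projection="polar")
    theta = 0.0
    cmap = plt.get_cmap("tab10")
    for i, cat in enumerate(spie.categories):
        width = spie.angles[i]
        ax.bar(theta + width / 2.0, spie.radii[i], width=width, bottom=0.0,
               color=cmap(i % 10), edgecolor="white", label=cat)
        theta += width
    ax.plot(np.linspace(0, 2 * np.pi, 200), np.ones(200), color="black", lw=0.8)
    ax.set_yticklabels([])
    ax.set_xticklabels([])
    ax.legend(loc="upper left", bbox_to_anchor=(1.0, 1.0), fontsize=7)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_run_summary(
    path: str | Path,
    config: Mapping[str, object],
    counter_lines: Sequence[str] = (),
) -> None:
    """Echo the effective configuration and ingest counters of a run."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"seqsketch {__version__} (python {sys.version.split()[0]})\n\n")
        fh.write("[config]\n")
        for key in sorted(config):
            fh.write(f"{key} = {config[key]}\n")
        if counter_lines:
            fh.write("\n[counters]\n")
            for line in counter_lines:
                fh.write(line + "\n")
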