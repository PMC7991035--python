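"""Manhattan and QQ plots for an association scan."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def manhattan_plot(assoc: pd.DataFrame, path: str | Path,
                   threshold: float = 3.5) -> None:
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(assoc.groupby("chrom")):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub["neg_log10_p"], s=4,
                   color="tab:blue" if i % 2 == 0 else "tab:orange")
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(chrom))
        offset += sub["pos"].max()
    ax.axhline(threshold, color="red", linestyle="--", linewidth=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(assoc: pd.DataFrame, path: str | Path) -> None:
    p = np.sort(assoc["p"].to_numpy())
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(expected, observed, s=4)
    lim = max(expected.max(), observed.max())
    ax.plot([0, lim], [0, lim], color="red", linewidth=0.8)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
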