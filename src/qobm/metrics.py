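"""Phase statistics: per-image SD distributions, nuclear CNR, Welch tests.

This is the quantitative-comparison layer: the acetowhitening effect shows
up as an overall decrease of the per-image phase standard deviation
(non-nuclear structure is homogenized) together with an increase in
nuclear contrast-to-noise.  Groups of images (fresh vs stained, real or
simulated) are summarized by their per-image SDs and compared pairwise
with two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .phantom import LABEL_BACKGROUND, LABEL_NUCLEUS
from .reconstruct import PhaseImage

__all__ = [
    "GroupSummary",
    "TTestResult",
    "phase_std",
    "nuclear_cnr",
    "welch_ttest",
    "group_summary",
    "plot_group_distributions",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-image phase SDs of one group of images, with summary scalars."""

    group_label: str
    per_image_sd: list[float]
    n: int
    mean_sd: float
    sd_of_sd: float


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t-test outcome (Welch by default; pooled optional)."""

    t_stat: float
    dof: float
    p_value: float
    group_sizes: tuple[int, int]


def _as_array(img) -> np.ndarray:
    return img.phase if isinstance(img, PhaseImage) else np.asarray(img, dtype=float)


def phase_std(img, mask: np.ndarray | None = None) -> float:
    """Sample standard deviation (n-1 denominator) of phase values.

    Computed over the whole image, or over ``mask`` if given.
    """
    values = _as_array(img)
    if mask is not None:
        if mask.shape != values.shape:
            raise ValueError("mask shape must match the image")
        values = values[mask.astype(bool)]
    values = values.ravel()
    if values.size < 2:
        raise ValueError("need at least 2 pixels to compute a standard deviation")
    return float(np.std(values, ddof=1))


def nuclear_cnr(img, labels: np.ndarray) -> float:
    """Nuclear contrast-to-noise ratio of a phase image.

    CNR = (mean over nucleus pixels - mean over background pixels)
    divided by the sample SD of the background pixels.
    """
    values = _as_array(img)
    if labels.shape != values.shape:
        raise ValueError("labels shape must match the image")
    nuc = values[labels == LABEL_NUCLEUS]
    bg = values[labels == LABEL_BACKGROUND]
    if nuc.size == 0 or bg.size < 2:
        raise ValueError("need non-empty nucleus and background classes")
    bg_sd = np.std(bg, ddof=1)
    if bg_sd == 0:
        raise ValueError("background SD is zero: CNR undefined")
    return float((nuc.mean() - bg.mean()) / bg_sd)


def welch_ttest(
    x: Sequence[float], y: Sequence[float], pooled: bool = False
) -> TTestResult:
    """Two-sided two-sample t-test.

    By default the Welch unequal-variance form: t = (x_bar - y_bar) /
    sqrt(s2x/nx + s2y/ny) with Welch-Satterthwaite degrees of freedom.
    ``pooled=True`` switches to the classical equal-variance Student test.
    The two-sided p-value comes from the Student-t CDF
    (``scipy.special.stdtr``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    s2x = x.var(ddof=1)
    s2y = y.var(ddof=1)
    if s2x == 0 and s2y == 0:
        raise ValueError("degenerate samples: both variances are zero")
    if pooled:
        dof = float(nx + ny - 2)
        sp2 = ((nx - 1) * s2x + (ny - 1) * s2y) / dof
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    else:
        vx, vy = s2x / nx, s2y / ny
        se = np.sqrt(vx + vy)
        dof = float(
            (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
        )
    t = float((x.mean() - y.mean()) / se)
    p = float(2.0 * special.stdtr(dof, -abs(t)))
    return TTestResult(t_stat=t, dof=dof, p_value=p, group_sizes=(nx, ny))


def group_summary(
    groups: Mapping[str, Sequence], pooled: bool = False, bonferroni: bool = False
) -> tuple[list[GroupSummary], pd.DataFrame, pd.DataFrame]:
    """Summarize groups of phase images by their per-image SDs.

    Returns ``(summaries, sd_table, ttest_table)``: one :class:`GroupSummary`
    per group, a long-format table (group, image_id, phase_sd), and all
    pairwise two-sample t-tests on the per-image SDs.  P-values are raw by
    default; ``bonferroni=True`` multiplies them by the number of pairs
    (clipped at 1).
    """
    summaries: list[GroupSummary] = []
    rows = []
    for label, images in groups.items():
        if len(images) < 2:
            raise ValueError(f"group {label!r} needs at least 2 images")
        sds = [phase_std(img) for img in images]
        summaries.append(
            GroupSummary(
                group_label=label,
                per_image_sd=sds,
                n=len(sds),
                mean_sd=float(np.mean(sds)),
                sd_of_sd=float(np.std(sds, ddof=1)),
            )
        )
        rows.extend(
            {"group": label, "image_id": i, "phase_sd": sd}
            for i, sd in enumerate(sds)
        )
    sd_table = pd.DataFrame(rows, columns=["group", "image_id", "phase_sd"])

    labels = [s.group_label for s in summaries]
    by_label = {s.group_label: s.per_image_sd for s in summaries}
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    trows = []
    for a, b in pairs:
        res = welch_ttest(by_label[a], by_label[b], pooled=pooled)
        p = res.p_value
        if bonferroni:
            p = min(1.0, p * len(pairs))
        trows.append(
            {"group_a": a, "group_b": b, "t": res.t_stat, "dof": res.dof, "p": p}
        )
    ttest_table = pd.DataFrame(trows, columns=["group_a", "group_b", "t", "dof", "p"])
    return summaries, sd_table, ttest_table


def plot_group_distributions(sd_table: pd.DataFrame, out_path) -> None:
    """Violin + strip plot of the per-image phase-SD distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(sd_table["group"].unique())
    data = [sd_table.loc[sd_table["group"] == g, "phase_sd"].values for g in labels]
    fig, ax = plt.subplots(figsize=(1.6 * max(len(labels), 2) + 1.5, 4))
    ax.violinplot(data, showmeans=True)
    for i, vals in enumerate(data, start=1):
        jitter = np.linspace(-0.08, 0.08, len(vals))
        ax.plot(i + jitter, vals, ".", color="k", alpha=0.4, markersize=3)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("per-image phase SD (rad)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
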