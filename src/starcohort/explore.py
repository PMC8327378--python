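"""Cohort exploration: demographic distributions, encounter-timeline
occupancy and feature-count-versus-threshold curves.

Everything here is tabular first — tidy data frames a notebook can plot
or a script can write to CSV; the optional matplotlib renderings are thin
layers on top and never required.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import features as features_mod
from .cohort import Cohort, DAYS_PER_YEAR
from .errors import ConfigError, DomainError
from .schema import DatabaseHandle, GENDERS

#: default relative-day windows around the anchor for the timeline matrix
DEFAULT_TIMELINE_WINDOWS = (
    (-365, -181),
    (-180, -31),
    (-30, -1),
    (0, 0),
    (1, 30),
    (31, 180),
    (181, 365),
)

#: default encounter-count bins; ``None`` is an open upper edge
DEFAULT_COUNT_BINS = ((0, 0), (1, 1), (2, 3), (4, 7), (8, None))


def _check_bins(bins: Sequence[tuple[int, int | None]]) -> None:
    if not bins:
        raise ConfigError("at least one count bin is required")
    expected_lo = 0
    for i, (lo, hi) in enumerate(bins):
        if lo != expected_lo:
            raise ConfigError(
                f"bins must be disjoint and exhaustive from 0; bin {i} starts at {lo}, "
                f"expected {expected_lo}"
            )
        if hi is None:
            if i != len(bins) - 1:
                raise ConfigError("only the last bin may be open-ended")
            return
        if hi < lo:
            raise ConfigError(f"bin {i} has upper edge {hi} below lower edge {lo}")
        expected_lo = hi + 1
    raise ConfigError("the last bin must be open-ended (upper edge None)")


def encounter_timeline(
    c: Cohort,
    windows: Sequence[tuple[int, int]] = DEFAULT_TIMELINE_WINDOWS,
    bins: Sequence[tuple[int, int | None]] = DEFAULT_COUNT_BINS,
) -> pd.DataFrame:
    """Fraction of patients per (relative-day window × encounter-count bin).

    A member falls into a bin when the number of its encounters
    *overlapping* the window (encounter ``[begin, end]`` intersecting
    ``[anchor+a, anchor+b]``) lies in the bin's inclusive range.  Bins
    must tile the non-negative integers, so every row sums to 1.
    """
    if not windows:
        raise ConfigError("at least one window is required")
    _check_bins(bins)
    if not len(c.members):
        raise DomainError("timeline is undefined for an empty cohort")
    with c.db.connect() as conn:
        enc = pd.read_sql_query(
            "SELECT patient_key, begin_day, end_day FROM d_encounter", conn
        )
    enc = enc[enc["patient_key"].isin(c.members)]
    labels = [_bin_label(b) for b in bins]
    rows = []
    for a, b in windows:
        if a > b:
            raise ConfigError(f"window start {a} exceeds end {b}")
        counts = {k: 0 for k in c.members}
        for pk, begin, end in enc.itertuples(index=False):
            anchor = c.anchors[int(pk)]
            if begin <= anchor + b and end >= anchor + a:
                counts[int(pk)] += 1
        row = {"window": f"[{a}, {b}]"}
        for (lo, hi), label in zip(bins, labels):
            n = sum(
                1 for v in counts.values() if v >= lo and (hi is None or v <= hi)
            )
            row[label] = n / len(c.members)
        rows.append(row)
    return pd.DataFrame(rows).set_index("window")


def _bin_label(b: tuple[int, int | None]) -> str:
    lo, hi = b
    if hi is None:
        return f"{lo}+"
    return str(lo) if lo == hi else f"{lo}-{hi}"


def feature_counts_by_threshold(
    c: Cohort,
    classes: Sequence[str],
    window: tuple[int, int],
    thresholds: Sequence[float],
    db: DatabaseHandle,
) -> pd.DataFrame:
    """Surviving feature count per (class × coverage threshold); the curve
    behind "how many features remain as the completeness bar rises"."""
    for t in thresholds:
        if not 0.0 <= t <= 1.0:
            raise ConfigError(f"threshold {t} outside [0, 1]")
    rows = []
    for cls in classes:
        cov = features_mod.feature_coverage(c, cls, window, db)
        for t in thresholds:
            rows.append(
                {
                    "condition_class": cls,
                    "threshold": float(t),
                    "n_features": int((cov["coverage"] >= t).sum()),
                }
            )
    return pd.DataFrame(rows)


def demography_tables(
    c: Cohort, age_bin_edges: Sequence[float] = tuple(range(0, 105, 5))
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gender histogram and age-at-anchor histogram for a cohort.

    Both histograms partition the membership: counts sum to ``len(c)``
    (ages outside the configured edges land in the edge bins).
    """
    from .cohort import _member_genders

    genders = _member_genders(c)
    gender_hist = pd.DataFrame(
        {
            "gender": list(GENDERS),
            "count": [sum(1 for g in genders.values() if g == target) for target in GENDERS],
        }
    )
    ages = np.array([c.anchors[k] for k in c.members], dtype=float) / DAYS_PER_YEAR
    edges = np.asarray(age_bin_edges, dtype=float)
    clipped = np.clip(ages, edges[0], np.nextafter(edges[-1], -np.inf)) if len(ages) else ages
    counts, _ = np.histogram(clipped, bins=edges)
    age_hist = pd.DataFrame(
        {
            "age_lo": edges[:-1],
            "age_hi": edges[1:],
            "count": counts.astype(int),
        }
    )
    return gender_hist, age_hist


def plot_encounter_timeline(timeline: pd.DataFrame, path: str | None = None):
    """Heatmap rendering of :func:`encounter_timeline` (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(timeline.columns) + 2, 0.5 * len(timeline) + 2))
    im = ax.imshow(timeline.to_numpy(), cmap="viridis", aspect="auto", vmin=0, vmax=1)
    ax.set_xticks(range(len(timeline.columns)), timeline.columns)
    ax.set_yticks(range(len(timeline)), timeline.index)
    ax.set_xlabel("encounters in window")
    ax.set_ylabel("days relative to anchor")
    for i in range(len(timeline)):
        for j in range(len(timeline.columns)):
            ax.text(j, i, f"{timeline.iat[i, j]:.2f}", ha="center", va="center",
                    color="white", fontsize=8)
    fig.colorbar(im, ax=ax, label="fraction of patients")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_demography(c: Cohort, path: str | None = None):
    """Bar plots of the gender and age distributions (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gender_hist, age_hist = demography_tables(c)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].bar(gender_hist["gender"], gender_hist["count"], color="#4c72b0")
    axes[0].set_title("gender")
    axes[0].set_ylabel("patients")
    centers = (age_hist["age_lo"] + age_hist["age_hi"]) / 2
    widths = age_hist["age_hi"] - age_hist["age_lo"]
    axes[1].bar(centers, age_hist["count"], width=widths * 0.9, color="#55a868")
    axes[1].set_title("age at anchor (years)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
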