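"""Optional figure helpers mirroring the assay's standard panel layout:
relative dry-mass curves, 12-h DMI bars and rounded-fraction bars per
condition."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["dm_curves", "dmi_bars", "rounded_fraction_bars"]


def _condition_label(row) -> str:
    c = row["concentration_ug_ml"]
    return row["condition"] if c == 0 else f"{row['condition']}"


def dm_curves(timeseries, path) -> None:
    """Mean relative dry-mass development (ng) per condition over time."""
    fig, ax = plt.subplots(figsize=(6, 4))
    g = timeseries.groupby(["condition", "time_h"])["dm_rel_pg"].mean().reset_index()
    for cond, d in g.groupby("condition"):
        ax.plot(d["time_h"], d["dm_rel_pg"] / 1000.0, marker="o", label=cond)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("relative dry mass DM (ng)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def dmi_bars(condition_summary, path) -> None:
    """12-h dry-mass increments (mean ± sd, ng) with significance stars."""
    cs = condition_summary.reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = [_condition_label(r) for _, r in cs.iterrows()]
    mean_ng = cs["dmi_mean_pg"] / 1000.0
    sd_ng = cs["dmi_sd_pg"].fillna(0.0) / 1000.0
    ax.bar(range(len(cs)), mean_ng, yerr=sd_ng, capsize=3)
    for i, (_, r) in enumerate(cs.iterrows()):
        stars = r.get("stars", "")
        if isinstance(stars, str) and stars:
            ax.text(i, mean_ng[i] + sd_ng[i], stars, ha="center")
    ax.set_xticks(range(len(cs)), labels, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("DMI (ng)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def rounded_fraction_bars(condition_summary, path) -> None:
    """Pooled 12-h fraction of rounded cells (C > 0.8) per condition."""
    cs = condition_summary.reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = [_condition_label(r) for _, r in cs.iterrows()]
    ax.bar(range(len(cs)), 100.0 * cs["rounded_fraction"])
    ax.set_xticks(range(len(cs)), labels, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("rounded cells (%)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
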