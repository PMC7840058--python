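"""Summary tables: box-plot quantiles and delimited-text output helpers.

Every table written by the pipeline carries a header comment with the run
seed and a hash of the configuration, so outputs are traceable to the
exact run that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rsfperm.dataset_io import AnalysisDataset


def summarize_boxplots(
    dataset: AnalysisDataset,
    attributes: Sequence[str],
    groups: pd.Series | None = None,
    truncation: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per group x attribute five-number summary.

    ``groups`` maps record_id to a display group (behavior type or
    "control"); by default controls form one group and each behavior its
    own.  Quartiles use linear interpolation between order statistics.
    Optional per-attribute truncation bounds (to tame extreme outliers in
    a plot) are recorded in the output rather than silently applied.
    """
    frame = dataset.frame
    if groups is None:
        groups = pd.Series(
            np.where(frame["role"] == "control", "control", frame["behavior"]),
            index=frame["record_id"],
        )
    labeled = frame.set_index("record_id").join(groups.rename("group"))

    rows = []
    for group, sub in labeled.groupby("group"):
        for attr in attributes:
            v = pd.to_numeric(sub[attr], errors="coerce")
            n_missing = int(v.isna().sum())
            v = v.dropna().to_numpy()
            lo, hi = (truncation or {}).get(attr, (-np.inf, np.inf))
            entry = {
                "group": group,
                "attribute": attr,
                "n": len(v),
                "n_missing": n_missing,
                "truncated_low": lo if np.isfinite(lo) else np.nan,
                "truncated_high": hi if np.isfinite(hi) else np.nan,
            }
            if len(v):
                q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
                entry.update(dict(zip(["min", "q1", "median", "q3", "max"], map(float, q))))
            else:
                entry.update({k: np.nan for k in ["min", "q1", "median", "q3", "max"]})
            rows.append(entry)
    return pd.DataFrame(rows)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
    index: bool = True,
    note: str | None = None,
) -> None:
    """Write a delimited table with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header_lines = []
    if seed is not None or cfg_hash is not None:
        header_lines.append(f"# seed={seed} config={cfg_hash}")
    if note:
        header_lines.append(f"# {note}")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def plot_ordination(result, labels: pd.Series, path: str | Path) -> None:
    """Scatter of the first two component scores by group, with solid group
    centroids, written as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = result.components[:2]
    scored = result.scores[comps].join(labels.rename("group"), how="inner")
    fig, ax = plt.subplots(figsize=(6, 5))
    for group, sub in scored.groupby("group"):
        pts = ax.scatter(sub[comps[0]], sub[comps[1]], s=12, alpha=0.35, label=str(group))
        ax.scatter(
            sub[comps[0]].mean(), sub[comps[1]].mean(),
            s=90, marker="D", color=pts.get_facecolor()[0][:3], edgecolor="black", zorder=3,
        )
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel(comps[0])
    ax.set_ylabel(comps[1])
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def inference_table(pooled) -> pd.DataFrame:
    """Combined fixed/random-effect summary for one behavior, in the layout
    of the study's results table (mean, standard error, p; random effects
    carry the fraction of permutations with a zero-variance fit)."""
    fixed = pooled.fixed_summary.copy()
    fixed.insert(0, "term_type", "fixed")
    rand = pooled.random_summary.rename(columns={"prob_zero": "p"}).copy()
    rand.insert(0, "term_type", "random")
    out = pd.concat([fixed, rand])
    out.index.name = "term"
    out.attrs["behavior"] = pooled.behavior
    out.attrs["n_retained"] = pooled.n_retained
    out.attrs["mean_accuracy"] = pooled.mean_accuracy
    return out
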