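"""Grayscale affected-fraction heatmaps and CSV exports for a fitted model."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .artifact import ModelArtifact


def affected_fraction_frame(artifact: ModelArtifact, community_id: int) -> pd.DataFrame:
    sp = artifact.subtype_profiles[community_id]
    return pd.DataFrame(sp.affected_fraction, index=sp.columns, columns=artifact.timepoints)


def population_frame(artifact: ModelArtifact) -> pd.DataFrame:
    """Total-population affected fraction, member-weighted over retained subtypes."""
    profs = artifact.retained_profiles()
    total = sum(sp.N_l for sp in profs)
    agg = sum(sp.affected_fraction * sp.N_l for sp in profs) / total
    return pd.DataFrame(agg, index=artifact.columns, columns=artifact.timepoints)


def _heatmap(frame: pd.DataFrame, title: str, path: str) -> None:
    fig, ax = plt.subplots(figsize=(4, 0.28 * len(frame) + 1.2))
    # dark = affected, matching the usual grayscale convention
    ax.imshow(frame.to_numpy(), cmap="Greys", vmin=0.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(frame.shape[1]), frame.columns)
    ax.set_yticks(range(frame.shape[0]), frame.index, fontsize=6)
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_report(artifact: ModelArtifact, out_dir) -> list[str]:
    """Write per-subtype and total-population heatmaps plus CSVs.

    Returns the list of files written.  With an empty retained set only the
    population panel is produced (from all labeled patients via U at
    baseline is unavailable, so the report notes the situation instead).
    """
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    for cid in sorted(artifact.subtype_profiles):
        frame = affected_fraction_frame(artifact, cid)
        sp = artifact.subtype_profiles[cid]
        csv = os.path.join(out_dir, f"subtype_{cid}_affected_fraction.csv")
        png = os.path.join(out_dir, f"subtype_{cid}_affected_fraction.png")
        frame.to_csv(csv)
        _heatmap(frame, f"Subtype {cid} (n={sp.N_l})", png)
        written += [csv, png]
    if artifact.subtype_profiles:
        frame = population_frame(artifact)
        csv = os.path.join(out_dir, "population_affected_fraction.csv")
        png = os.path.join(out_dir, "population_affected_fraction.png")
        frame.to_csv(csv)
        _heatmap(frame, "Total population", png)
        written += [csv, png]
    else:
        note = os.path.join(out_dir, "REPORT_NOTE.txt")
        with open(note, "w") as fh:
            fh.write("No retained subtypes; nothing to render.\n")
        written.append(note)
    return written
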