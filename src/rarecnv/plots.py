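"""Diagnostic plots: consensus overlap histogram, z-density fit, depth ratios.

All functions save a PNG and return the path; matplotlib's Agg backend is
forced so they work headless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import CnvCall
from .qc import overlap_fraction


def plot_overlap_histogram(
    primary_calls: Sequence[CnvCall],
    secondary_calls: Sequence[CnvCall],
    path: str | Path,
) -> Path:
    """Histogram of the best secondary-caller overlap fraction per primary
    call — the diagnostic behind the 10% consensus threshold."""
    by_sample: dict[str, list[CnvCall]] = {}
    for c in secondary_calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    fracs = []
    for call in primary_calls:
        candidates = [
            overlap_fraction(call, o)
            for o in by_sample.get(call.sample_id, [])
            if o.is_deletion == call.is_deletion
        ]
        fracs.append(max(candidates, default=0.0))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(fracs, bins=20, range=(0, 1), color="steelblue", edgecolor="white")
    ax.axvline(0.10, color="firebrick", linestyle="--", label="consensus threshold")
    ax.set_xlabel("best same-direction overlap fraction")
    ax.set_ylabel("primary calls")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_z_densities(
    observed_z: np.ndarray, permuted_z: np.ndarray, path: str | Path
) -> Path:
    """Observed gene-set statistics against the permutation null density."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(
        permuted_z.ravel(), bins=40, density=True, alpha=0.5,
        color="grey", label="permutation null",
    )
    ax.hist(
        np.asarray(observed_z), bins=25, density=True, histtype="step",
        color="firebrick", label="observed",
    )
    ax.set_xlabel("set statistic z")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_depth_ratios(
    ratios: Sequence[float], copy_numbers: Sequence[int], path: str | Path
) -> Path:
    """Depth-ratio histogram coloured by assigned copy number."""
    ratios = np.asarray(ratios, dtype=float)
    cn = np.asarray(copy_numbers)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for k in sorted(set(cn.tolist())):
        ax.hist(ratios[cn == k], bins=30, alpha=0.7, label=f"copy number {k}")
    ax.set_xlabel("depth ratio")
    ax.set_ylabel("samples")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
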