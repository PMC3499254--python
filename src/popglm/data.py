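"""Containers and text I/O for trial-binned spike counts and covariates.

A recording session is reduced to a trials x neurons matrix of nonnegative
integer spike counts, one count per neuron per trial (or time bin), together
with a table of per-trial external covariates (movement direction, hand
speed, 2-D position, tone log-frequency) and an optional discrete condition
label per trial.  Counts are written as plain delimited text with a YAML
sidecar carrying bin duration, condition labels and provenance, so every
dataset on disk is self-describing and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["SpikeCounts", "CovariateTable", "write_dataset", "read_dataset"]


@dataclass
class SpikeCounts:
    """Trial-by-trial spike counts for a simultaneously recorded population.

    Parameters
    ----------
    counts : ndarray of shape (n_trials, n_neurons)
        Nonnegative integer spike counts, one bin per trial.
    bin_duration : float
        Duration of the counting window in seconds (e.g. 0.2 for a 200 ms
        peri-movement window).
    condition_labels : ndarray of shape (n_trials,), optional
        Discrete condition identifier per trial (e.g. one of 8 reach
        targets).  Required by the within-condition shuffle control.
    """

    counts: np.ndarray
    bin_duration: float
    condition_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (trials x neurons)")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("spike counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.bin_duration <= 0:
            raise ValueError("bin_duration must be positive")
        if self.condition_labels is not None:
            self.condition_labels = np.asarray(self.condition_labels)
            if len(self.condition_labels) != self.n_trials:
                raise ValueError("need one condition label per trial")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    def mean_rates(self) -> np.ndarray:
        """Mean firing rate per neuron in Hz."""
        return self.counts.mean(axis=0) / self.bin_duration


# Covariate columns understood by the basis builders, with units.
KNOWN_COVARIATES = {
    "direction": "degrees",
    "speed": "cm/s",
    "pos_x": "cm",
    "pos_y": "cm",
    "log_frequency": "octaves",
}


@dataclass
class CovariateTable:
    """Per-trial external variables with semantic tags.

    Wraps a DataFrame with one row per trial.  Recognised columns are
    ``direction`` (degrees, reduced modulo 360), ``speed`` (cm/s), ``pos_x``
    / ``pos_y`` (cm) and ``log_frequency`` (octaves).  Unrecognised columns
    are carried along untouched.
    """

    table: pd.DataFrame
    tags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.table = pd.DataFrame(self.table).reset_index(drop=True)
        if not self.tags:
            self.tags = tuple(
                c for c in self.table.columns if c in KNOWN_COVARIATES
            )
        if "direction" in self.table.columns:
            self.table["direction"] = np.mod(self.table["direction"], 360.0)

    @property
    def n_trials(self) -> int:
        return len(self.table)

    def __getitem__(self, column: str) -> np.ndarray:
        if column not in self.table.columns:
            raise KeyError(
                f"covariate {column!r} not present; available: "
                f"{list(self.table.columns)}"
            )
        return self.table[column].to_numpy()

    def has(self, column: str) -> bool:
        return column in self.table.columns


def write_dataset(
    prefix: str | Path,
    counts: SpikeCounts,
    covariates: CovariateTable | None = None,
    spec: dict | None = None,
) -> None:
    """Write a dataset as ``<prefix>_counts.tsv`` (+ covariates, sidecar).

    The sidecar ``<prefix>_meta.yaml`` records bin duration, condition
    labels, covariate columns, and the generating spec/seed when the data
    are simulated, so a run can be reproduced from the files alone.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        counts.counts, columns=[f"n{j}" for j in range(counts.n_neurons)]
    ).to_csv(prefix.parent / f"{prefix.name}_counts.tsv", sep="\t", index=False)
    meta: dict = {"bin_duration": float(counts.bin_duration)}
    if counts.condition_labels is not None:
        meta["condition_labels"] = [
            int(c) if np.issubdtype(type(c), np.integer) else str(c)
            for c in counts.condition_labels
        ]
    if covariates is not None:
        covariates.table.to_csv(
            prefix.parent / f"{prefix.name}_covariates.tsv", sep="\t", index=False
        )
        meta["covariate_columns"] = list(covariates.table.columns)
    if spec is not None:
        meta["generating_spec"] = spec
    with open(prefix.parent / f"{prefix.name}_meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_dataset(prefix: str | Path) -> tuple[SpikeCounts, CovariateTable | None]:
    """Read a dataset written by :func:`write_dataset`."""
    prefix = Path(prefix)
    counts_path = prefix.parent / f"{prefix.name}_counts.tsv"
    meta_path = prefix.parent / f"{prefix.name}_meta.yaml"
    if not counts_path.exists():
        raise FileNotFoundError(counts_path)
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    counts = pd.read_csv(counts_path, sep="\t").to_numpy(dtype=np.int64)
    labels = meta.get("condition_labels")
    sc = SpikeCounts(
        counts,
        bin_duration=float(meta["bin_duration"]),
        condition_labels=np.asarray(labels) if labels is not None else None,
    )
    cov_path = prefix.parent / f"{prefix.name}_covariates.tsv"
    cov = None
    if cov_path.exists():
        cov = CovariateTable(pd.read_csv(cov_path, sep="\t"))
    return sc, cov
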