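"""In-memory containers shared across the pipeline stages.

The central object is :class:`ProbeLevelMatrix`: a probes × samples intensity
matrix together with the probe → probe-set map and the sample → group map.
All downstream stages (normalization, model-based expression indices, the
SAM screen, the probe-consistency filter) consume or produce views of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ProbeLevelMatrix", "ExpressionIndexTable"]


@dataclass
class ProbeLevelMatrix:
    """Probe-level intensities with probe-set membership and sample groups.

    Parameters
    ----------
    intensities
        Probes × samples matrix of non-negative intensities. The index holds
        probe ids, the columns sample ids.
    probe_map
        Series mapping probe id → probe-set id. Every probe in
        ``intensities`` must appear exactly once.
    sample_groups
        Series mapping sample id → group label. Every sample (column) must
        have a group.
    """

    intensities: pd.DataFrame
    probe_map: pd.Series
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if self.intensities.isna().any().any():
            raise ValueError("intensity matrix contains missing values")
        if self.intensities.index.has_duplicates:
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise ValueError(f"duplicate probe id in intensity matrix: {dup!r}")
        if self.probe_map.index.has_duplicates:
            dup = self.probe_map.index[self.probe_map.index.duplicated()][0]
            raise ValueError(f"probe {dup!r} appears more than once in probe map")
        missing = self.intensities.index.difference(self.probe_map.index)
        if len(missing):
            raise ValueError(f"probe {missing[0]!r} missing from probe map")
        unknown = self.intensities.columns.difference(self.sample_groups.index)
        if len(unknown):
            raise ValueError(f"sample {unknown[0]!r} missing from sample sheet")
        # align maps to the matrix
        self.probe_map = self.probe_map.loc[self.intensities.index]
        self.sample_groups = self.sample_groups.loc[self.intensities.columns]

    # -- convenience accessors -------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.intensities.columns

    @property
    def probes(self) -> pd.Index:
        return self.intensities.index

    @property
    def probeset_ids(self) -> list:
        """Probe-set ids in first-appearance order of their probes."""
        return list(dict.fromkeys(self.probe_map.values))

    def probes_of(self, probeset_id) -> pd.Index:
        return self.probe_map.index[self.probe_map.values == probeset_id]

    def samples_in_group(self, group) -> pd.Index:
        return self.sample_groups.index[self.sample_groups.values == group]

    @property
    def groups(self) -> list:
        """Group labels in sample order (deduplicated)."""
        return list(dict.fromkeys(self.sample_groups.values))

    def subset_probesets(self, probeset_ids) -> "ProbeLevelMatrix":
        wanted = set(probeset_ids)
        keep = self.probe_map.index[[g in wanted for g in self.probe_map.values]]
        return ProbeLevelMatrix(
            intensities=self.intensities.loc[keep],
            probe_map=self.probe_map.loc[keep],
            sample_groups=self.sample_groups.copy(),
        )


@dataclass
class ExpressionIndexTable:
    """Model-based expression indices and per-probe-set fit diagnostics.

    ``theta`` holds the expression index θ_i per probe set and sample,
    ``phi`` the per-probe affinities φ_j (Σ_j φ_j² = J within each probe
    set). Diagnostics record the residual standard deviation, outlier flags,
    convergence status and iteration counts of the alternating-least-squares
    fit.
    """

    theta: pd.DataFrame           # probe sets × samples
    phi: pd.Series                # probe id → affinity
    residual_sd: pd.Series        # probe set → residual SD
    outlier_flags: pd.DataFrame   # probes × samples, boolean
    converged: pd.Series          # probe set → bool
    iterations: pd.Series         # probe set → int
    probe_map: pd.Series = field(repr=False, default=None)

    def diagnostics(self) -> pd.DataFrame:
        """Per-probe-set diagnostics table (for TSV export)."""
        if self.probe_map is not None:
            counts = self.outlier_flags.groupby(self.probe_map).sum().sum(axis=1)
            n_outliers = counts.reindex(self.theta.index).fillna(0).astype(int)
        else:
            n_outliers = pd.Series(0, index=self.theta.index)
        return pd.DataFrame(
            {
                "residual_sd": self.residual_sd,
                "iterations": self.iterations,
                "converged": self.converged,
                "n_outliers": n_outliers,
            }
        )
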