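"""Statsmodels-style modelling interface.

``GroupNetworkModel`` holds a multi-subject grayordinate dataset together
with the analysis settings (rank, synchronization and optimizer options);
``fit()`` runs group synchronization, stacks the tensor and solves the CP
network model, returning a ``GroupNetworkResults`` that carries the
decomposition, fit diagnostics and the downstream map/statistics operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import GrayordinateDataset
from .decomposition import (
    DataTensor,
    Decomposition,
    NascarOptions,
    build_tensor,
    explained_variance,
    nascar_decompose,
)
from .maps import NetworkMaps, build_network_maps
from .roistats import ROIAtlas, ROIStatsTable, summarize_rois
from .seed import SeedCorrelationMap, seed_correlation_map
from .sync import SyncResult, group_brainsync

__all__ = ["GroupNetworkModel", "GroupNetworkResults"]


@dataclass
class GroupNetworkModel:
    """CP brain-network model for a group of synchronized subjects.

    Parameters
    ----------
    dataset
        Row-normalized multi-subject data.
    rank
        Number of CP components to extract.  The convention for real data is
        a deliberately over-estimated bound (R = 30); small desk-scale runs
        use single digits.
    options
        Optimizer settings (:class:`NascarOptions`).
    sync, sync_tol, sync_max_iter
        Whether/how to run group synchronization before stacking.  Disable
        only for data already expressed in a common temporal frame.
    """

    dataset: GrayordinateDataset
    rank: int = 8
    options: NascarOptions = field(default_factory=NascarOptions)
    sync: bool = True
    sync_tol: float = 1e-6
    sync_max_iter: int = 20

    @classmethod
    def from_hdf5(cls, path, **kwargs) -> "GroupNetworkModel":
        return cls(dataset=GrayordinateDataset.from_hdf5(path), **kwargs)

    def fit(self, seed: int = 0) -> "GroupNetworkResults":
        """Synchronize, stack and decompose; deterministic given ``seed``."""
        if self.sync:
            sync_result = group_brainsync(
                self.dataset, tol=self.sync_tol, max_iter=self.sync_max_iter
            )
            synced = sync_result.synced
        else:
            sync_result = None
            synced = self.dataset
        tensor = build_tensor(synced, synced=True)
        decomposition = nascar_decompose(
            tensor, rank=self.rank, opts=self.options, seed=seed
        )
        return GroupNetworkResults(
            model=self,
            sync_result=sync_result,
            tensor=tensor,
            decomposition=decomposition,
        )


@dataclass
class GroupNetworkResults:
    """Fitted group network model: components, diagnostics, downstream maps."""

    model: GroupNetworkModel
    sync_result: SyncResult | None
    tensor: DataTensor
    decomposition: Decomposition

    @property
    def explained_variance(self) -> float:
        """Total variance fraction captured by all components together."""
        return explained_variance(self.decomposition, self.tensor)

    def component_variances(self) -> np.ndarray:
        """Per-component explained-variance fraction (components in isolation)."""
        normx2 = float(np.sum(self.tensor.values**2))
        out = np.empty(self.decomposition.rank)
        x1 = self.tensor.values.reshape(self.tensor.shape[0], -1)
        for i, c in enumerate(self.decomposition.components):
            kr = np.outer(c.temporal, c.subject).ravel()
            cross = c.magnitude * float(c.spatial @ (x1 @ kr))
            out[i] = (2.0 * cross - c.magnitude**2) / normx2
        return out

    def summary(self) -> str:
        """Human-readable fit summary table."""
        var = self.component_variances()
        df = pd.DataFrame(
            {
                "component": np.arange(self.decomposition.rank),
                "magnitude": self.decomposition.magnitudes,
                "var_fraction": var,
            }
        )
        lines = [
            "Group network model (CP decomposition)",
            f"  subjects: {self.tensor.shape[2]}   timepoints: {self.tensor.shape[1]}"
            f"   grayordinates: {self.tensor.shape[0]}",
            f"  rank: {self.decomposition.rank}   "
            f"explained variance: {self.explained_variance:.4f}",
            f"  synchronized: {self.sync_result is not None}"
            + (
                f" (iterations: {self.sync_result.n_iterations}, "
                f"converged: {self.sync_result.converged})"
                if self.sync_result is not None
                else ""
            ),
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def network_maps(
        self,
        template: np.ndarray,
        quantile: float = 0.95,
        upsample_factor: int = 2,
    ) -> NetworkMaps:
        """Select the template-matching network and build its maps."""
        return build_network_maps(
            self.decomposition,
            template,
            self.model.dataset,
            quantile=quantile,
            upsample_factor=upsample_factor,
        )

    def roi_statistics(
        self,
        maps: NetworkMaps,
        atlas: ROIAtlas,
        roi_region_pairs: list[tuple[str, str]],
        fwhm_mm: float = 2.0,
        alphas: tuple[float, float] = (0.05, 0.001),
    ) -> ROIStatsTable:
        """ROI table of the normalized subcortical map (at the upsampled
        resolution; the atlas is nearest-neighbour upsampled to match)."""
        atlas_hi = atlas.upsampled(maps.upsample_factor)
        return summarize_rois(
            maps.upsampled_volume, atlas_hi, roi_region_pairs,
            fwhm_mm=fwhm_mm, alphas=alphas,
        )

    def seed_map(self, seed_index: int, gsr: bool = False) -> SeedCorrelationMap:
        """Seed-based comparison map on the model's (unsynchronized) data —
        full-window correlations are unchanged by synchronization."""
        return seed_correlation_map(self.model.dataset, seed_index, gsr=gsr)
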