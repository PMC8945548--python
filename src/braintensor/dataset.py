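"""Multi-subject grayordinate dataset container.

A *grayordinate* dataset samples the brain as one spatial index set that mixes
cortical surface vertices and subcortical volume voxels.  Each subject
contributes a ``(V, T)`` matrix of BOLD time series on that common sampling.
The container keeps the cortical/subcortical partition and, for the
subcortical part, the integer 3-D grid coordinates needed to rebuild volumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["GrayordinateDataset"]


@dataclass
class GrayordinateDataset:
    """Per-subject space x time BOLD matrices with a cortical/subcortical split.

    Parameters
    ----------
    subjects
        List of ``(V, T)`` float arrays, one per subject, all the same shape.
    cortical_index, subcortical_index
        Disjoint integer index sets into the space axis whose union covers
        ``0..V-1``.
    subcortical_grid_coords
        ``(len(subcortical_index), 3)`` integer voxel coordinates of each
        subcortical grayordinate on its 3-D grid.
    grid_dims
        Shape of the subcortical voxel grid.
    subject_ids
        Optional labels; generated as ``sub-000..`` when omitted.
    """

    subjects: list[np.ndarray]
    cortical_index: np.ndarray
    subcortical_index: np.ndarray
    subcortical_grid_coords: np.ndarray
    grid_dims: tuple[int, int, int]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.subjects = [np.asarray(x, dtype=float) for x in self.subjects]
        self.cortical_index = np.asarray(self.cortical_index, dtype=int)
        self.subcortical_index = np.asarray(self.subcortical_index, dtype=int)
        self.subcortical_grid_coords = np.asarray(
            self.subcortical_grid_coords, dtype=int
        )
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(len(self.subjects))]
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_vertices(self) -> int:
        return self.subjects[0].shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.subjects[0].shape[1]

    def validate(self) -> None:
        if not self.subjects:
            raise ValueError("dataset has no subjects")
        shape = self.subjects[0].shape
        for i, x in enumerate(self.subjects):
            if x.ndim != 2 or x.shape != shape:
                raise ValueError(
                    f"subject {i} has shape {x.shape}, expected {shape}"
                )
        if len(self.subject_ids) != len(self.subjects):
            raise ValueError("subject_ids length mismatch")
        v = shape[0]
        overlap = np.intersect1d(self.cortical_index, self.subcortical_index)
        if overlap.size:
            raise ValueError("cortical and subcortical index sets overlap")
        union = np.union1d(self.cortical_index, self.subcortical_index)
        if union.size != v or (np.sort(union) != np.arange(v)).any():
            raise ValueError(
                "cortical and subcortical indices must partition the space axis"
            )
        if self.subcortical_grid_coords.shape != (self.subcortical_index.size, 3):
            raise ValueError("subcortical_grid_coords must be (n_subcortical, 3)")

    # ------------------------------------------------------------------
    def subset(self, subject_positions: np.ndarray) -> "GrayordinateDataset":
        """Dataset restricted to the given subject positions (copies views)."""
        pos = np.asarray(subject_positions, dtype=int)
        return dataclasses.replace(
            self,
            subjects=[self.subjects[i] for i in pos],
            subject_ids=[self.subject_ids[i] for i in pos],
        )

    def stacked(self) -> np.ndarray:
        """All subjects stacked along a trailing axis, shape ``(V, T, S)``."""
        return np.stack(self.subjects, axis=2)

    # ------------------------------------------------------------------
    # HDF5 container: one file with /subjects/<id> 2-D arrays, index sets and
    # grid metadata at the root.
    def to_hdf5(self, path, **attrs) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("subjects")
            for sid, x in zip(self.subject_ids, self.subjects):
                g.create_dataset(sid, data=x)
            f.create_dataset("cortical_index", data=self.cortical_index)
            f.create_dataset("subcortical_index", data=self.subcortical_index)
            f.create_dataset(
                "subcortical_grid_coords", data=self.subcortical_grid_coords
            )
            f.attrs["grid_dims"] = np.asarray(self.grid_dims, dtype=int)
            f.attrs["subject_order"] = [s.encode() for s in self.subject_ids]
            for k, v in attrs.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "GrayordinateDataset":
        with h5py.File(path, "r") as f:
            order = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f.attrs["subject_order"]
            ]
            subjects = [f["subjects"][sid][()] for sid in order]
            return cls(
                subjects=subjects,
                cortical_index=f["cortical_index"][()],
                subcortical_index=f["subcortical_index"][()],
                subcortical_grid_coords=f["subcortical_grid_coords"][()],
                grid_dims=tuple(int(d) for d in f.attrs["grid_dims"]),
                subject_ids=order,
            )
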