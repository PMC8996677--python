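"""Volume and atlas I/O, smoothing, SUVR normalization, ROI extraction.

Bridges image space to the subjects x ROI matrix that all network
estimation consumes.  Volumes and integer label atlases are NIfTI-1 files
(read/written through nibabel); SUVR matrices are delimited text with one
row per subject.

The atlas and every volume are assumed to share one voxel grid — spatial
normalization is upstream of this package and out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class Volume:
    """A 3D intensity grid with voxel spacing and an affine for round-trips."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if np.isnan(self.data).any():
            raise ValueError("volume contains NaN voxels")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @classmethod
    def load(cls, path, allow_nan_mask: bool = False) -> "Volume":
        """Read a NIfTI volume.  NaN voxels are rejected unless
        ``allow_nan_mask`` is set, in which case they are replaced by 0 and
        the caller is expected to exclude them via an ROI mask."""
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        if np.isnan(data).any():
            if not allow_nan_mask:
                raise ValueError(f"{path}: NaN voxels present")
            data = np.nan_to_num(data, nan=0.0)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=data, spacing=spacing, affine=np.asarray(img.affine))

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float64), self.affine), str(path))


@dataclass
class ROIAtlas:
    """Integer label grid (0 = background) plus ROI metadata."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    reference_label: int | None = None
    modules: dict[int, int] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise ValueError("atlas labels must be integers")
            self.labels = self.labels.astype(int)
        present = self.roi_labels()
        if not self.names:
            self.names = {int(l): f"ROI_{l}" for l in present}
        missing = [int(l) for l in present if int(l) not in self.names]
        if missing:
            raise ValueError(f"labels missing from names table: {missing}")
        if self.reference_label is not None:
            if not (self.labels == self.reference_label).any():
                raise ValueError(f"reference label {self.reference_label} has no voxels")

    def roi_labels(self) -> np.ndarray:
        """Sorted nonzero labels, excluding the reference region."""
        labs = np.unique(self.labels)
        labs = labs[labs > 0]
        if self.reference_label is not None:
            labs = labs[labs != self.reference_label]
        return labs

    @classmethod
    def load(cls, path, names=None, reference_label=None, modules=None) -> "ROIAtlas":
        img = nib.load(str(path))
        labels = np.asanyarray(img.dataobj)
        return cls(labels=np.round(labels).astype(int), names=names or {},
                   reference_label=reference_label, modules=modules)

    def save(self, path, spacing=(1.0, 1.0, 1.0)) -> None:
        affine = np.diag(list(spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))


@dataclass
class SUVRMatrix:
    """Subjects x ROI table of normalized uptake, with group labels."""

    values: np.ndarray
    subject_ids: list
    roi_labels: list
    group: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (subjects x ROI)")
        n, p = self.values.shape
        if len(self.subject_ids) != n or len(self.roi_labels) != p:
            raise ValueError("subject/ROI label lengths must match values shape")
        if self.group.shape != (n,):
            raise ValueError("group must have one label per subject")
        if np.isnan(self.values).any():
            raise ValueError("SUVR matrix contains NaN")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def select_group(self, label) -> "SUVRMatrix":
        m = self.group == label
        return SUVRMatrix(
            values=self.values[m],
            subject_ids=[s for s, keep in zip(self.subject_ids, m) if keep],
            roi_labels=self.roi_labels,
            group=self.group[m],
            covariates=None if self.covariates is None else self.covariates.loc[m].reset_index(drop=True),
        )

    def select_rois(self, labels) -> "SUVRMatrix":
        idx = [self.roi_labels.index(l) for l in labels]
        return SUVRMatrix(
            values=self.values[:, idx],
            subject_ids=self.subject_ids,
            roi_labels=list(labels),
            group=self.group,
            covariates=self.covariates,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(l) for l in self.roi_labels])
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "group", self.group)
        if self.covariates is not None:
            for c in self.covariates.columns:
                df[c] = np.asarray(self.covariates[c])
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, covariate_columns=("age", "sex")) -> "SUVRMatrix":
        df = pd.read_csv(path)
        cov_cols = [c for c in covariate_columns if c in df.columns]
        roi_cols = [c for c in df.columns if c not in ("subject_id", "group", *cov_cols)]
        roi_labels = []
        for c in roi_cols:
            try:
                roi_labels.append(int(c))
            except ValueError:
                roi_labels.append(c)
        return cls(
            values=df[roi_cols].to_numpy(dtype=float),
            subject_ids=list(df["subject_id"]),
            roi_labels=roi_labels,
            group=df["group"].to_numpy(),
            covariates=df[cov_cols].reset_index(drop=True) if cov_cols else None,
        )


def smooth_volume(v: Volume, fwhm_mm: float, mode: str = "reflect") -> Volume:
    """Separable Gaussian smoothing with a kernel given in mm FWHM.

    Per-axis sigma (in voxels) is fwhm / (2*sqrt(2 ln 2)) / spacing, so
    anisotropic voxels are handled correctly.  Reflect padding preserves
    constants in the interior and approximately conserves total intensity.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = [fwhm_mm / FWHM_PER_SIGMA / s for s in v.spacing]
    out = ndimage.gaussian_filter(v.data, sigma=sigma_vox, mode=mode)
    return Volume(data=out, spacing=v.spacing, affine=v.affine)


def compute_suvr(v: Volume, atlas: ROIAtlas) -> Volume:
    """Divide every voxel by the mean intensity over the reference region.

    The reference region (cerebellar gray matter in typical FDG-PET use)
    is the atlas voxel set with label ``atlas.reference_label``.
    """
    if atlas.reference_label is None:
        raise ValueError("atlas has no reference_label for SUVR normalization")
    if atlas.labels.shape != v.data.shape:
        raise ValueError("atlas grid does not match volume grid")
    ref = v.data[atlas.labels == atlas.reference_label]
    if ref.size == 0:
        raise ValueError("reference region is empty")
    m = ref.mean()
    if m <= 0:
        raise ValueError(f"reference region mean is non-positive ({m})")
    return Volume(data=v.data / m, spacing=v.spacing, affine=v.affine)


def extract_roi_matrix(
    volumes: list[Volume],
    atlas: ROIAtlas,
    subject_ids=None,
    group=None,
    covariates: pd.DataFrame | None = None,
) -> SUVRMatrix:
    """Mean signal per ROI per subject; columns follow sorted atlas labels."""
    labels = atlas.roi_labels()
    if labels.size == 0:
        raise ValueError("atlas defines no ROIs")
    for lab in labels:
        if not (atlas.labels == lab).any():  # pragma: no cover - roi_labels implies presence
            raise ValueError(f"ROI label {lab} has no voxels")
    n = len(volumes)
    if subject_ids is None:
        subject_ids = [f"sub-{i+1:03d}" for i in range(n)]
    if group is None:
        group = np.array(["all"] * n)
    vals = np.empty((n, labels.size))
    masks = [atlas.labels == lab for lab in labels]
    for s, v in enumerate(volumes):
        if v.data.shape != atlas.labels.shape:
            raise ValueError(f"subject {subject_ids[s]}: volume grid does not match atlas")
        for r, mask in enumerate(masks):
            vals[s, r] = v.data[mask].mean()
    return SUVRMatrix(
        values=vals,
        subject_ids=list(subject_ids),
        roi_labels=[int(l) for l in labels],
        group=np.asarray(group),
        covariates=covariates,
    )


def read_roi_metadata(path) -> pd.DataFrame:
    """ROI metadata CSV: label, name, optional x/y/z (mm) and module."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("ROI metadata must contain a 'label' column")
    return df
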