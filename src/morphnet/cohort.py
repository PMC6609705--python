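"""In-memory cohort container: per-subject, per-view, per-ROI cortical attributes.

A *view* is one cortical attribute measured on every ROI of one hemisphere
(e.g. mean cortical thickness).  The cohort holds a complete ``N x M x R``
array of ROI means together with subject ages and diagnostic group labels.
Hemispheres are never mixed inside one cohort: left- and right-hemisphere
data form separate cohorts and separate analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["CorticalAttributeCohort", "DEFAULT_VIEW_NAMES", "GROUP_NC", "GROUP_DISORDERED"]

GROUP_NC = "NC"
GROUP_DISORDERED = "DISORDERED"

#: Canonical view order for the four-attribute configuration.
DEFAULT_VIEW_NAMES = (
    "max_principal_curvature",
    "mean_cortical_thickness",
    "mean_sulcal_depth",
    "mean_average_curvature",
)


@dataclass
class CorticalAttributeCohort:
    """Validated cohort of per-ROI cortical attribute means.

    Parameters
    ----------
    subject_ids
        Unique subject identifiers, length ``N``.
    ages
        Chronological ages in years, nonnegative, length ``N``.
    groups
        Diagnostic labels, each ``"NC"`` or ``"DISORDERED"``, length ``N``.
    hemisphere
        ``"LH"`` or ``"RH"``; one cohort covers exactly one hemisphere.
    attributes
        Array of shape ``(N, M, R)``: subject x view x ROI mean values.
    view_names
        Ordered view labels, length ``M``.
    roi_mask
        Optional boolean length-``R`` array; ``False`` marks a ROI that is
        excluded from all views when features are built.  Default keeps all.
    """

    subject_ids: list[str]
    ages: np.ndarray
    groups: list[str]
    hemisphere: str
    attributes: np.ndarray
    view_names: tuple[str, ...] = ()
    roi_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.attributes = np.asarray(self.attributes, dtype=float)
        if self.attributes.ndim != 3:
            raise ValueError(
                f"attributes must be N x M x R, got shape {self.attributes.shape}"
            )
        n, m, r = self.attributes.shape
        if not self.view_names:
            if m == len(DEFAULT_VIEW_NAMES):
                self.view_names = DEFAULT_VIEW_NAMES
            else:
                self.view_names = tuple(f"view{i + 1}" for i in range(m))
        self.view_names = tuple(self.view_names)
        if len(self.view_names) != m:
            raise ValueError(
                f"{len(self.view_names)} view names for {m} attribute views"
            )
        if len(self.subject_ids) != n or len(self.ages) != n or len(self.groups) != n:
            raise ValueError("subject_ids, ages, groups and attributes disagree on N")
        if len(set(self.subject_ids)) != n:
            seen: set[str] = set()
            dup = next(s for s in self.subject_ids if s in seen or seen.add(s))
            raise ValueError(f"duplicate subject ID {dup!r}")
        if self.hemisphere not in ("LH", "RH"):
            raise ValueError(f"hemisphere must be 'LH' or 'RH', got {self.hemisphere!r}")
        bad_groups = sorted(set(self.groups) - {GROUP_NC, GROUP_DISORDERED})
        if bad_groups:
            raise ValueError(f"unknown group labels {bad_groups}")
        if not np.all(np.isfinite(self.ages)) or np.any(self.ages < 0):
            raise ValueError("ages must be finite and nonnegative")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != (r,):
                raise ValueError("roi_mask must be a length-R boolean array")
        # Non-finite attribute values are only legal on masked-out ROIs.
        bad = ~np.isfinite(self.attributes)
        if self.roi_mask is not None:
            bad = bad[:, :, self.roi_mask]
        if np.any(bad):
            k, m_, i = np.argwhere(~np.isfinite(self.attributes))[0]
            raise ValueError(
                f"non-finite attribute for subject {self.subject_ids[k]!r}, "
                f"view {self.view_names[m_]!r}, ROI index {i + 1}"
            )

    @property
    def n_subjects(self) -> int:
        return self.attributes.shape[0]

    @property
    def n_views(self) -> int:
        return self.attributes.shape[1]

    @property
    def n_rois(self) -> int:
        return self.attributes.shape[2]

    def subset(self, index: Sequence[int] | np.ndarray) -> "CorticalAttributeCohort":
        """Row-subset the cohort by 0-based subject positions."""
        index = np.asarray(index)
        return CorticalAttributeCohort(
            subject_ids=[self.subject_ids[i] for i in index],
            ages=self.ages[index],
            groups=[self.groups[i] for i in index],
            hemisphere=self.hemisphere,
            attributes=self.attributes[index],
            view_names=self.view_names,
            roi_mask=None if self.roi_mask is None else self.roi_mask.copy(),
        )

    def nc_only(self) -> "CorticalAttributeCohort":
        """Subset to normal-control subjects."""
        idx = [i for i, g in enumerate(self.groups) if g == GROUP_NC]
        return self.subset(idx)
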