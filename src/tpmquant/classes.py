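"""Structure-class label codes shared across the pipeline.

Every pixel of a classified image carries exactly one of five labels:
extracellular background (``outside``), intracellular background
(``cytoplasm``), or one of the three F-actin structure classes the
quantification targets (endocytic ``patch``, linear ``cable``,
cytokinetic ``ring``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

OUTSIDE = 0
CYTOPLASM = 1
PATCH = 2
CABLE = 3
RING = 4

CLASS_NAMES: dict[int, str] = {
    OUTSIDE: "outside",
    CYTOPLASM: "cytoplasm",
    PATCH: "patch",
    CABLE: "cable",
    RING: "ring",
}
CLASS_CODES: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}

STRUCTURE_CLASSES = (PATCH, CABLE, RING)

#: sentinel for unannotated pixels in sparse training label images
UNLABELLED = 255


@dataclass
class LabelImage:
    """Per-pixel structure-class map for one field of view.

    Parameters
    ----------
    labels : ndarray of uint8, shape (Y, X)
        One class code per pixel (see module constants).
    provenance : dict
        Which channel role produced each structure class, e.g.
        ``{"patch": "factin", "cable": "tpm", "ring": "tpm"}``.
        Ground-truth label images use ``"ground_truth"`` for all classes.
    """

    labels: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2D, got shape {self.labels.shape}")
        valid = set(CLASS_NAMES)
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown class codes {sorted(present - valid)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code
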