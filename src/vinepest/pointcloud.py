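"""Point-cloud container with LAS-style class codes.

The photogrammetric dense cloud is the geometric input of the pipeline.
Class codes follow the ASPRS LAS specification subset the method uses:
2 = ground, 4 = medium vegetation, 7 = (low) noise, 0/1 = unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PointCloud",
    "CLASS_UNCLASSIFIED",
    "CLASS_GROUND",
    "CLASS_MEDIUM_VEGETATION",
    "CLASS_NOISE",
]

CLASS_UNCLASSIFIED = 1
CLASS_GROUND = 2
CLASS_MEDIUM_VEGETATION = 4
CLASS_NOISE = 7

_KNOWN_CLASSES = frozenset(
    {0, CLASS_UNCLASSIFIED, CLASS_GROUND, CLASS_MEDIUM_VEGETATION, CLASS_NOISE}
)


@dataclass
class PointCloud:
    """``xyz`` is ``(n, 3)`` float64 meters; ``rgb`` optional ``(n, 3)``
    uint8; ``classification`` optional ``(n,)`` uint8 LAS class codes."""

    xyz: np.ndarray
    rgb: np.ndarray | None = None
    classification: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=np.float64))
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb, dtype=np.uint8)
            if self.rgb.shape != self.xyz.shape:
                raise ValueError("rgb must match xyz shape")
        if self.classification is not None:
            self.classification = np.asarray(self.classification, dtype=np.uint8)
            if self.classification.shape != (len(self),):
                raise ValueError("classification must be (n,)")
            unknown = set(np.unique(self.classification)) - _KNOWN_CLASSES
            if unknown:
                raise ValueError(f"unknown LAS class codes: {sorted(unknown)}")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def subset(self, index) -> "PointCloud":
        return PointCloud(
            self.xyz[index],
            rgb=None if self.rgb is None else self.rgb[index],
            classification=None
            if self.classification is None
            else self.classification[index],
        )

    def with_classification(self, classification: np.ndarray) -> "PointCloud":
        return PointCloud(self.xyz, rgb=self.rgb, classification=classification)

    def class_counts(self) -> dict[int, int]:
        if self.classification is None:
            return {}
        codes, counts = np.unique(self.classification, return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts)}
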