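"""Image-stack container and TIFF/JSON persistence.

Stacks are stored as multi-frame grayscale TIFF (16-bit unsigned, one file
per channel) with a JSON sidecar carrying acquisition metadata and, for
simulated data, the full ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError

__all__ = ["ImageStack", "write_stack", "read_stack"]


@dataclass
class ImageStack:
    """frames × rows × cols array of camera counts plus acquisition metadata.

    ``pixel_size`` is in nm/pixel; ``frame_interval`` in seconds (None for
    continuous photobleach acquisitions); ``exposure`` in ms.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float | None = None
    exposure: float | None = None
    channel: str = "yfp"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise FormatError(f"expected frames × rows × cols, got shape {self.frames.shape}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size * 1e-3


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path, ground_truth=None) -> Path:
    """Write a stack as 16-bit grayscale multi-frame TIFF with a JSON sidecar.

    Counts are clipped into [0, 65535] and rounded.  ``ground_truth`` may be
    any JSON-serializable mapping (see :meth:`GroundTruth.to_dict`).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.rint(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "pixel_size_nm": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "exposure_ms": stack.exposure,
        "channel": stack.channel,
        "metadata": stack.metadata,
    }
    if ground_truth is not None:
        meta["ground_truth"] = ground_truth if isinstance(ground_truth, dict) else ground_truth.to_dict()
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path) -> ImageStack:
    """Read a multi-frame grayscale TIFF written by :func:`write_stack`.

    Raises :class:`FormatError` for RGB/multi-sample pages or corrupt files;
    no partial silent reads.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                if page.samplesperpixel != 1:
                    raise FormatError(
                        f"page {i} of {path.name} has {page.samplesperpixel} samples/pixel; "
                        "expected grayscale"
                    )
            frames = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:  # corrupt/truncated file
        raise FormatError(f"cannot parse TIFF {path}: {exc}") from exc
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ImageStack(
        frames=frames,
        pixel_size=meta.get("pixel_size_nm", float("nan")),
        frame_interval=meta.get("frame_interval_s"),
        exposure=meta.get("exposure_ms"),
        channel=meta.get("channel", "yfp"),
        metadata={k: v for k, v in meta.items() if k not in {"pixel_size_nm", "frame_interval_s", "exposure_ms", "channel"}},
    )
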