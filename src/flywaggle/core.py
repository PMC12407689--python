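"""Core data containers shared across the flywaggle pipeline.

The pipeline operates on two-fly pose tracks (four body nodes per fly:
head, thorax, left and right wing tip), a multichannel microphone trace,
and sequences of labelled behavioral bouts.  Frame intervals are half-open,
0-based ``[start, end)`` everywhere; durations in seconds are
``(end - start) / fps``.  Coordinates are stored in millimetres in memory
(pixels on disk), with the image convention x right / y down.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NODE_NAMES: tuple[str, ...] = ("head", "thorax", "wing_l", "wing_r")
FLY_IDS: tuple[str, ...] = ("male", "female")
BEHAVIORS: tuple[str, ...] = ("stillness", "waggle", "song", "other")
#: behaviors for which no dominant wing is defined
WINGLESS_BEHAVIORS = frozenset({"stillness", "other"})
#: tolerated input spellings, normalised on read (strict on write)
BEHAVIOR_ALIASES = {"singing": "song", "waggling": "waggle", "still": "stillness"}
WINGS: tuple[str, ...] = ("left", "right", "none")


def normalize_behavior(name: str) -> str:
    """Map a behavior label (or declared alias) to its canonical name."""
    name = name.strip().lower()
    name = BEHAVIOR_ALIASES.get(name, name)
    if name not in BEHAVIORS:
        raise ValueError(f"unknown behavior label {name!r}; expected one of {BEHAVIORS}")
    return name


@dataclass(frozen=True)
class RecordingMeta:
    """Immutable per-recording metadata.

    Defaults follow the study's recording setup: 150 fps video at
    30.3 pixels/mm and 10 kHz audio.
    """

    recording_id: str
    fps: float = 150.0
    audio_sr: int = 10_000
    px_per_mm: float = 30.3
    n_frames: int = 1
    n_flies: int = 2
    species_tag: str = "synthetic"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.audio_sr <= 0:
            raise ValueError("audio_sr must be > 0")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_flies not in (1, 2):
            raise ValueError("n_flies must be 1 or 2")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class PoseTrack:
    """Per-fly pose through a recording.

    Attributes
    ----------
    fly_id : str
        ``"male"`` or ``"female"``.
    coords : ndarray, shape (n_frames, 4, 2)
        Node positions in mm, ordered as :data:`NODE_NAMES`.  Missing
        entries are NaN.
    mask : ndarray, shape (n_frames, 4), bool
        True where the node was tracked on that frame.
    """

    fly_id: str
    coords: np.ndarray
    mask: np.ndarray
    nodes: tuple[str, ...] = NODE_NAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.nodes), 2):
            raise ValueError(
                f"coords must have shape (n_frames, {len(self.nodes)}, 2), "
                f"got {self.coords.shape}"
            )
        if self.mask.shape != self.coords.shape[:2]:
            raise ValueError("mask shape must be (n_frames, n_nodes)")
        if tuple(self.nodes) != NODE_NAMES:
            raise ValueError(f"nodes must be exactly {NODE_NAMES}")
        bad = self.mask & ~np.isfinite(self.coords).all(axis=-1)
        if bad.any():
            raise ValueError("non-finite coordinates flagged as present in mask")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def node_index(self, name: str) -> int:
        try:
            return self.nodes.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}") from None

    def node(self, name: str) -> np.ndarray:
        """Return the (n_frames, 2) coordinate series for one node."""
        return self.coords[:, self.node_index(name), :]

    def copy(self) -> "PoseTrack":
        return PoseTrack(self.fly_id, self.coords.copy(), self.mask.copy(), self.nodes)


@dataclass(frozen=True)
class BoutRecord:
    """A labelled half-open frame interval ``[start, end)`` of one behavior."""

    recording_id: str
    behavior: str
    start: int
    end: int
    dominant_wing: str = "none"
    provenance: str = "detected"

    def __post_init__(self) -> None:
        object.__setattr__(self, "behavior", normalize_behavior(self.behavior))
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid bout interval [{self.start}, {self.end})")
        if self.dominant_wing not in WINGS:
            raise ValueError(f"dominant_wing must be one of {WINGS}")
        if (self.behavior in WINGLESS_BEHAVIORS) != (self.dominant_wing == "none"):
            raise ValueError(
                f"dominant_wing={self.dominant_wing!r} inconsistent with "
                f"behavior={self.behavior!r}"
            )
        if self.provenance not in ("detected", "truth", "manual"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    def duration_s(self, fps: float) -> float:
        return (self.end - self.start) / fps

    def iou(self, other: "BoutRecord") -> float:
        """Temporal intersection-over-union with another interval."""
        inter = min(self.end, other.end) - max(self.start, other.start)
        if inter <= 0:
            return 0.0
        union = max(self.end, other.end) - min(self.start, other.start)
        return inter / union

    def with_(self, **kwargs) -> "BoutRecord":
        return replace(self, **kwargs)


@dataclass
class Ethogram:
    """Ordered, non-overlapping bout sequence for one recording.

    ``bouts`` holds the retained bouts after duration filtering;
    ``frame_labels`` (optional) keeps the full per-frame labelling, and
    ``n_excluded`` counts bouts dropped by the duration thresholds.
    """

    recording_id: str
    fps: float
    n_frames: int
    bouts: list[BoutRecord] = field(default_factory=list)
    frame_labels: np.ndarray | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        prev_end = 0
        for b in self.bouts:
            if b.start < prev_end:
                raise ValueError("bouts must be ordered and non-overlapping")
            if b.end > self.n_frames:
                raise ValueError("bout extends past the recording")
            prev_end = b.end

    @property
    def labels(self) -> list[str]:
        return [b.behavior for b in self.bouts]

    def select(self, behavior: str) -> list[BoutRecord]:
        behavior = normalize_behavior(behavior)
        return [b for b in self.bouts if b.behavior == behavior]
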