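"""File formats and run manifests.

Images travel as multi-page TIFF with a JSON sidecar carrying the
acquisition metadata (µm/pixel, frame interval) — metadata is never
silently defaulted.  Tables are tidy CSV; run manifests are JSON with
config snapshot, input hashes, and every stage seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


def write_image_stack(stack: np.ndarray, path: str | Path,
                      metadata: dict | None = None) -> None:
    """Write a 2D image or 3D stack as (multi-page) TIFF + JSON sidecar."""
    path = Path(path)
    stack = np.asarray(stack)
    kwargs = {"photometric": "minisblack"} if stack.ndim >= 3 else {}
    tifffile.imwrite(path, stack, **kwargs)
    if metadata is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(metadata, indent=1))


def read_image_stack(path: str | Path, require_metadata: bool = False):
    """Read a TIFF (single- or multi-page) and its sidecar metadata.

    Raises a KeyError naming the expected sidecar when
    ``require_metadata`` is set and no sidecar exists — resolution is
    never silently assumed.
    """
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    elif require_metadata:
        raise KeyError(
            f"missing metadata sidecar {sidecar.name}: supply pixel_size_um / "
            "frame_interval_min in the sidecar or the config's imaging section")
    return data, meta


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    stages: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)

    def add_stage(self, name: str, **outputs) -> None:
        self.stages.append(name)
        self.outputs[name] = {k: str(v) for k, v in outputs.items()}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config,
            "seed": self.seed,
            "stages": self.stages,
            "outputs": self.outputs,
            "input_hashes": self.input_hashes,
        }, indent=1, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        raw = json.loads(Path(path).read_text())
        m = cls(config=raw["config"], seed=raw["seed"])
        m.stages = raw["stages"]
        m.outputs = raw["outputs"]
        m.input_hashes = raw.get("input_hashes", {})
        return m
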