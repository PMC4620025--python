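"""File formats: single-channel TIFF stacks and matrix containers.

Matrices travel in two forms: a plain-text format with a one-line header
(round-trips to full double precision) and a binary ``.npz`` container
(bit-exact round-trip). Label masks are written as 16-bit TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "FormatError",
    "read_tiff_stack",
    "write_tiff_stack",
    "write_label_mask",
    "write_matrix",
    "read_matrix",
    "write_ground_truth",
]

_TEXT_MAGIC = "topocode-matrix"


class FormatError(ValueError):
    """Unsupported or corrupt file contents."""


def read_tiff_stack(path: str | Path) -> list[np.ndarray]:
    """Read an 8- or 16-bit single-channel TIFF as a list of 2-D frames."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        frames = [arr]
    elif arr.ndim == 3 and arr.shape[-1] not in (3, 4):
        frames = [arr[i] for i in range(arr.shape[0])]
    else:
        raise FormatError(
            f"expected single-channel 2-D pages, got array of shape {arr.shape} "
            "(multi-channel/RGB TIFF is not supported)"
        )
    for f in frames:
        if f.dtype not in (np.uint8, np.uint16):
            raise FormatError(f"unsupported TIFF sample type {f.dtype} (need uint8/uint16)")
    return frames


def write_tiff_stack(path: str | Path, frames: list[np.ndarray]) -> None:
    if not frames:
        raise ValueError("cannot write an empty stack")
    stack = np.stack(frames)
    if stack.dtype not in (np.uint8, np.uint16):
        raise ValueError("frames must be uint8 or uint16")
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label ids out of 16-bit range")
    tifffile.imwrite(str(path), labels.astype(np.uint16), photometric="minisblack")


def write_matrix(path: str | Path, matrix: np.ndarray, name: str = "matrix") -> None:
    """Write a 2-D matrix; ``.npz`` gives a bit-exact binary round-trip,
    any other suffix a delimited-text form with a one-line header."""
    path = Path(path)
    M = np.asarray(matrix, dtype=np.float64)
    if M.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite entries")
    if path.suffix == ".npz":
        np.savez(path, values=M, name=np.array(name))
    else:
        header = f"{_TEXT_MAGIC} name={name} rows={M.shape[0]} cols={M.shape[1]}"
        np.savetxt(path, M, fmt="%.17e", header=header)


def read_matrix(path: str | Path) -> tuple[np.ndarray, str]:
    path = Path(path)
    if path.suffix == ".npz":
        try:
            with np.load(path) as z:
                return z["values"], str(z["name"])
        except Exception as exc:  # truncated/foreign file
            raise FormatError(f"cannot read binary matrix {path}: {exc}") from exc
    try:
        with open(path) as fh:
            first = fh.readline()
    except OSError as exc:
        raise FormatError(str(exc)) from exc
    if not first.startswith("# " + _TEXT_MAGIC):
        raise FormatError(f"{path} lacks the matrix header line")
    fields = dict(
        kv.split("=", 1) for kv in first[2:].strip().split()[1:] if "=" in kv
    )
    try:
        rows, cols = int(fields["rows"]), int(fields["cols"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed matrix header in {path}") from exc
    M = np.loadtxt(path, ndmin=2)
    if M.shape != (rows, cols):
        raise FormatError(
            f"{path}: header promises {rows}x{cols} but file holds {M.shape}"
        )
    return M, fields.get("name", "matrix")


def write_ground_truth(path: str | Path, scenes) -> None:
    """Ground truth as delimited text: frame_id, cell_id, phase, row, col."""
    with open(path, "w") as fh:
        fh.write("frame_id\tcell_id\tphase\trow\tcol\n")
        for frame_id, scene in enumerate(scenes):
            for cell_id, (phase, (r, c)) in enumerate(
                zip(scene.phases, scene.centroids), start=1
            ):
                fh.write(f"{frame_id}\t{cell_id}\t{phase}\t{r:.3f}\t{c:.3f}\n")
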