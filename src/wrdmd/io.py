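"""Readers and writers for image stacks, masks and result tables.

Supported stack formats: multi-page TIFF, a directory of PNG/TIFF frames
(ordered by name), and NIfTI-1 volumes whose third axis is time. Masks are
read from PNG (nonzero = in-ROI) or NIfTI. Intensities are promoted to
float64 on read; stacks are written as float32 multi-page TIFF.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import FormatError, InvalidInputError
from .frames import FrameStack
from .phantom import PhantomOutput
from .roi import ROIMask

__all__ = [
    "read_sequence",
    "write_sequence",
    "read_mask",
    "write_mask_png",
    "write_eigenvalue_table",
    "write_mode_images",
    "export_phantom",
]

_FRAME_SUFFIXES = (".png", ".tif", ".tiff")


def _read_tiff_stack(path: Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 2-D or 3-D TIFF, got shape {arr.shape}")
    return arr


def _read_frame_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if not files:
        raise FormatError(f"{path}: no PNG/TIFF frames found")
    frames = []
    shape = None
    for f in files:
        try:
            img = np.asarray(iio.imread(f))
        except Exception as exc:  # noqa: BLE001 - rewrap with the file named
            raise FormatError(f"{f}: unreadable image ({exc})") from exc
        if img.ndim == 3:  # collapse an RGB(A) frame to grayscale
            img = img[..., :3].mean(axis=-1)
        if img.ndim != 2:
            raise FormatError(f"{f}: expected a 2-D frame, got shape {img.shape}")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise FormatError(
                f"{f}: frame size {img.shape} differs from first frame {shape}"
            )
        frames.append(img)
    return np.stack(frames)


def _read_nifti_stack(path: Path) -> np.ndarray:
    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D NIfTI (m, n, time), got {vol.shape}")
    return np.transpose(vol, (2, 0, 1))


def read_sequence(path, fmt: str | None = None, dt: float = 1.5) -> FrameStack:
    """Read a dynamic sequence as a :class:`FrameStack`.

    ``fmt`` is one of ``"tiff"``, ``"dir"``, ``"nifti"`` or ``None`` to
    detect from the path: a directory reads as named frames in lexicographic
    order; ``.nii``/``.nii.gz`` as a NIfTI stack with time on axis 3;
    anything else as a multi-page TIFF.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file or directory")
    if fmt is None:
        if path.is_dir():
            fmt = "dir"
        elif path.name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        else:
            fmt = "tiff"
    readers = {"tiff": _read_tiff_stack, "dir": _read_frame_dir, "nifti": _read_nifti_stack}
    if fmt not in readers:
        raise InvalidInputError(f"unknown sequence format {fmt!r}")
    return FrameStack(readers[fmt](path).astype(np.float64), dt=dt)


def write_sequence(path, stack: FrameStack) -> None:
    """Write a stack as a float32 multi-page TIFF."""
    tifffile.imwrite(Path(path), stack.data.astype(np.float32))


def read_mask(path) -> ROIMask:
    """Read a binary ROI mask from PNG (nonzero = in-ROI) or NIfTI."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.name.endswith((".nii", ".nii.gz")):
        arr = np.asanyarray(nib.load(str(path)).dataobj)
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
    else:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., :3].max(axis=-1)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D mask, got shape {arr.shape}")
    return ROIMask(arr != 0)


def write_mask_png(path, mask: ROIMask) -> None:
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))


def write_eigenvalue_table(path, decomp, ordering=None) -> pd.DataFrame:
    """CSV table of eigenvalues: index, Re/Im, magnitude, phase, frequency,
    and whether the mode survives conjugate pruning."""
    kept = set()
    if ordering is not None:
        kept = set(int(i) for i in ordering.kept_indices)
    eig = decomp.eigenvalues
    df = pd.DataFrame(
        {
            "index": np.arange(decomp.n_modes),
            "re_sigma": eig.real,
            "im_sigma": eig.imag,
            "abs_sigma": np.abs(eig),
            "phase": np.angle(eig),
            "re_mu": decomp.frequencies.real,
            "im_mu": decomp.frequencies.imag,
            "kept": [i in kept for i in range(decomp.n_modes)],
        }
    )
    df.to_csv(path, index=False)
    return df


def _normalise_u8(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return ((img - lo) / (hi - lo) * 255).astype(np.uint8)


def write_mode_images(outdir, decomp, indices, prefix: str = "mode") -> None:
    """Write selected mode images: raw real part as float TIFF plus a
    min–max normalised 8-bit PNG preview (modes have arbitrary scale/sign)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for j in indices:
        img = decomp.mode_image(int(j)).real
        tifffile.imwrite(outdir / f"{prefix}_{int(j):03d}.tif", img.astype(np.float32))
        iio.imwrite(outdir / f"{prefix}_{int(j):03d}.png", _normalise_u8(img))


def export_phantom(outdir, phantom: PhantomOutput) -> dict[str, Path]:
    """Write a phantom to disk: frames (TIFF), masks (PNG), motion trace and
    truth curves (CSV), and the generating configuration (YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["stack"] = outdir / "phantom.tif"
    write_sequence(paths["stack"], phantom.stack)

    mask_dir = outdir / "masks"
    mask_dir.mkdir(exist_ok=True)
    for name, mask in phantom.masks.items():
        p = mask_dir / f"{name}.png"
        write_mask_png(p, mask)
        paths[f"mask_{name}"] = p

    paths["motion_trace"] = outdir / "motion_trace.csv"
    pd.DataFrame(
        {
            "frame_index": np.arange(phantom.stack.n_frames),
            "dr_px": phantom.motion_trace[:, 0],
            "dc_px": phantom.motion_trace[:, 1],
        }
    ).to_csv(paths["motion_trace"], index=False)

    paths["truth_curves"] = outdir / "truth_curves.csv"
    truth = pd.DataFrame({"frame_index": np.arange(phantom.stack.n_frames)})
    for name, values in phantom.curve_truth.items():
        truth[name] = values
    truth.to_csv(paths["truth_curves"], index=False)

    cfg = phantom.config
    paths["config"] = outdir / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                "frame_shape": list(cfg.frame_shape),
                "n_frames": cfg.n_frames,
                "dt": cfg.dt,
                "background": cfg.background,
                "texture_amplitude": cfg.texture_amplitude,
                "texture_smoothness_px": cfg.texture_smoothness_px,
                "noise_sd": cfg.noise_sd,
                "seed": cfg.seed,
                "motion": {
                    "amplitude_px": cfg.motion.amplitude_px,
                    "period_frames": cfg.motion.period_frames,
                    "axis": cfg.motion.axis,
                    "waveform": cfg.motion.waveform,
                    "drift_px_per_frame": cfg.motion.drift_px_per_frame,
                    "integer_shifts": cfg.motion.integer_shifts,
                },
                "regions": [
                    {
                        "name": r.name,
                        "shape": r.shape,
                        "centre": list(r.centre),
                        "axes": list(r.axes),
                        "enhancement": {
                            "amplitude": r.enhancement.amplitude,
                            "onset_s": r.enhancement.onset_s,
                            "time_to_peak_s": r.enhancement.time_to_peak_s,
                            "alpha": r.enhancement.alpha,
                        },
                    }
                    for r in cfg.regions
                ],
            },
            fh,
            sort_keys=False,
        )
    return paths
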