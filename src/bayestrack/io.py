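"""File round-tripping: TIFF stacks, track CSVs, metadata and chain files."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import tifffile

from .likelihood import CameraEMCCD, CameraSPAD, ImageStack
from .sampler import ChainState, PosteriorSamples, SamplerConfig
from .motion import CandidateSet, MotionParams
from .optics import OpticsConfig

__all__ = [
    "write_stack",
    "read_stack",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_chain",
    "read_chain",
    "camera_to_dict",
    "camera_from_dict",
]

TRACK_COLUMNS = ["frame", "candidate", "x_nm", "y_nm", "load"]


def camera_to_dict(camera) -> dict:
    if isinstance(camera, CameraSPAD):
        return {"model": "spad"}
    if isinstance(camera, CameraEMCCD):
        return {
            "model": "emccd",
            "offset": camera.offset,
            "em_gain": camera.em_gain,
            "read_noise_sd": camera.read_noise_sd,
            "excess_noise_factor_sq": camera.excess_noise_factor_sq,
        }
    raise TypeError(f"unsupported camera: {camera!r}")


def camera_from_dict(block: dict):
    block = dict(block)
    model = block.pop("model", None)
    if model == "spad":
        if block:
            raise ValueError(f"unknown keys in SPAD camera block: {sorted(block)}")
        return CameraSPAD()
    if model == "emccd":
        allowed = {"offset", "em_gain", "read_noise_sd", "excess_noise_factor_sq"}
        unknown = set(block) - allowed
        if unknown:
            raise ValueError(f"unknown keys in EMCCD camera block: {sorted(unknown)}")
        return CameraEMCCD(**block)
    raise ValueError(f"camera block must set model to 'spad' or 'emccd', got {model!r}")


def optics_to_dict(optics: OpticsConfig) -> dict:
    return asdict(optics)


def optics_from_dict(block: dict) -> OpticsConfig:
    allowed = {
        "numerical_aperture",
        "refractive_index",
        "emission_wavelength_nm",
        "pixel_size_nm",
        "psf_sigma_factor",
    }
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in optics block: {sorted(unknown)}")
    return OpticsConfig(**block)


def write_stack(
    path: str | Path,
    stack: ImageStack,
    camera=None,
    optics: Optional[OpticsConfig] = None,
    extra_metadata: Optional[dict] = None,
) -> None:
    """Write a multi-page TIFF plus a JSON metadata sidecar (same stem)."""
    path = Path(path)
    values = stack.values
    if values.dtype not in (np.uint8, np.uint16):
        raise ValueError("stack values must be uint8 (SPAD) or uint16 (EMCCD ADU)")
    tifffile.imwrite(path, values, photometric="minisblack")
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "exposure_s": stack.exposure_s,
        "n_frames": stack.n_frames,
        "frame_shape": list(stack.frame_shape),
    }
    if camera is not None:
        meta["camera"] = camera_to_dict(camera)
    if optics is not None:
        meta["optics"] = optics_to_dict(optics)
    if extra_metadata:
        meta.update(extra_metadata)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_stack(path: str | Path):
    """Read a TIFF stack and its JSON sidecar.

    Returns ``(stack, camera_or_None, optics_or_None, metadata_dict)``.
    """
    path = Path(path)
    values = tifffile.imread(path)
    if values.ndim == 2:
        values = values[None]
    meta_path = path.with_suffix(".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    stack = ImageStack(
        values=values,
        pixel_size_nm=float(meta["pixel_size_nm"]),
        exposure_s=float(meta["exposure_s"]),
    )
    expected_shape = (meta["n_frames"], *meta["frame_shape"])
    if stack.values.shape != tuple(expected_shape):
        raise ValueError(
            f"stack shape {stack.values.shape} does not match metadata {expected_shape}"
        )
    camera = camera_from_dict(meta["camera"]) if "camera" in meta else None
    optics = optics_from_dict(meta["optics"]) if "optics" in meta else None
    return stack, camera, optics, meta


def write_tracks_csv(path: str | Path, positions: np.ndarray, loads=None) -> None:
    """Write (N, K, 2) positions (and optional loads) as a long-format CSV."""
    positions = np.asarray(positions, dtype=float)
    n_frames, n_cand = positions.shape[0], positions.shape[1]
    if loads is None:
        loads = np.ones(n_cand, dtype=int)
    frames, cands = np.meshgrid(
        np.arange(n_frames), np.arange(n_cand), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "frame": frames.ravel(),
            "candidate": cands.ravel(),
            "x_nm": positions[..., 0].ravel(),
            "y_nm": positions[..., 1].ravel(),
            "load": np.broadcast_to(np.asarray(loads, dtype=int), (n_frames, n_cand)).ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_tracks_csv(path: str | Path):
    """Read a track CSV back into ``(positions (N,K,2), loads (K,))``."""
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    n_frames = int(df["frame"].max()) + 1
    n_cand = int(df["candidate"].max()) + 1
    positions = np.full((n_frames, n_cand, 2), np.nan)
    loads = np.zeros(n_cand, dtype=np.int8)
    positions[df["frame"], df["candidate"], 0] = df["x_nm"]
    positions[df["frame"], df["candidate"], 1] = df["y_nm"]
    loads[df["candidate"]] = df["load"]
    if np.any(np.isnan(positions)):
        raise ValueError("track CSV does not cover every (frame, candidate) pair")
    return positions, loads


def _config_to_json(config: SamplerConfig) -> str:
    return json.dumps(asdict(config), sort_keys=True)


def _config_from_json(text: str) -> SamplerConfig:
    return SamplerConfig(**json.loads(text))


def write_chain(path: str | Path, samples: PosteriorSamples) -> None:
    """Write thinned samples (and the resumable final state) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("iterations", data=samples.iterations)
        f.create_dataset("loads", data=samples.loads)
        f.create_dataset("tracks", data=samples.tracks)
        f.create_dataset("msd", data=samples.msd)
        f.create_dataset("background", data=samples.background)
        f.create_dataset("brightness", data=samples.brightness)
        f.create_dataset("logpost", data=samples.log_posterior)
        f.create_dataset("logpost_trace", data=samples.log_posterior_trace)
        f.attrs["config"] = _config_to_json(samples.config)
        if samples.final_state is not None:
            g = f.create_group("final_state")
            st = samples.final_state
            g.create_dataset("positions", data=st.candidates.positions)
            g.create_dataset("loads", data=st.candidates.loads)
            g.attrs["msd"] = st.motion.msd_per_frame_nm2
            g.attrs["background_rate"] = st.background_rate
            g.attrs["brightness"] = st.brightness
            g.attrs["iteration"] = st.iteration


def read_chain(path: str | Path) -> PosteriorSamples:
    with h5py.File(path, "r") as f:
        config = _config_from_json(f.attrs["config"])
        final_state = None
        if "final_state" in f:
            g = f["final_state"]
            final_state = ChainState(
                candidates=CandidateSet(g["positions"][...], g["loads"][...]),
                motion=MotionParams(float(g.attrs["msd"])),
                background_rate=float(g.attrs["background_rate"]),
                brightness=float(g.attrs["brightness"]),
                iteration=int(g.attrs["iteration"]),
            )
        return PosteriorSamples(
            iterations=f["iterations"][...],
            loads=f["loads"][...],
            tracks=f["tracks"][...],
            msd=f["msd"][...],
            background=f["background"][...],
            brightness=f["brightness"][...],
            log_posterior=f["logpost"][...],
            log_posterior_trace=f["logpost_trace"][...],
            config=config,
            final_state=final_state,
        )
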