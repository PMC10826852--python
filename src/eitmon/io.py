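"""Measurement-frame and configuration IO.

Frames are exchanged as CSV (one row per injection, one column per
differential channel, metadata in ``#`` header lines) or as HDF5 bundles;
experiment configurations are TOML files with ``[phantom]``, ``[grid]`` and
``[experiment]`` tables.
"""

from __future__ import annotations

import pathlib

import h5py
import numpy as np

from .detect import ExperimentConfig, ScenarioGrid, build_grid
from .forward import CurrentPatternSet, MeasurementFrame
from .phantom import HEALTHY, HeadPhantomSpec

__all__ = [
    "save_frame_csv",
    "load_frame_csv",
    "save_frames_h5",
    "load_frames_h5",
    "load_run_config",
]


def save_frame_csv(path, frame: MeasurementFrame, patterns: CurrentPatternSet) -> None:
    """Write a frame as CSV: one row per injection, one column per channel."""
    P, L = patterns.n_patterns, patterns.n_electrodes
    if frame.V.size != P * L:
        raise ValueError("frame does not cover the full injection × channel grid")
    V = frame.V.reshape(P, L)
    lines = [
        f"# label={frame.label}",
        f"# noise_std={frame.noise_std!r}",
        f"# seed={frame.seed}",
        f"# pattern={patterns.descriptor}",
        ",".join(f"ch_{c + 1}_{(c + 1) % L + 1}" for c in range(L)),
    ]
    lines += [",".join(f"{v:.12e}" for v in row) for row in V]
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def load_frame_csv(path) -> MeasurementFrame:
    meta = {}
    rows = []
    for line in pathlib.Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
        elif line and not line.startswith("ch_"):
            rows.append([float(v) for v in line.split(",")])
    V = np.asarray(rows).ravel()
    seed = meta.get("seed")
    return MeasurementFrame(
        V=V,
        noise_std=float(meta.get("noise_std", 0.0)),
        label=meta.get("label", "t1"),
        seed=None if seed in (None, "None") else int(seed),
    )


def save_frames_h5(path, frames: dict, patterns: CurrentPatternSet) -> None:
    """Store several frames plus the injection patterns in one HDF5 file."""
    with h5py.File(path, "w") as fh:
        g = fh.create_group("patterns")
        g.create_dataset("matrix", data=patterns.matrix)
        g.attrs["descriptor"] = patterns.descriptor
        fg = fh.create_group("frames")
        for name, frame in frames.items():
            sub = fg.create_group(str(name))
            sub.create_dataset("V", data=frame.V)
            if frame.noise_free is not None:
                sub.create_dataset("noise_free", data=frame.noise_free)
            sub.attrs["noise_std"] = frame.noise_std
            sub.attrs["label"] = frame.label
            sub.attrs["seed"] = -1 if frame.seed is None else frame.seed


def load_frames_h5(path) -> tuple[dict, CurrentPatternSet]:
    with h5py.File(path, "r") as fh:
        patterns = CurrentPatternSet(
            fh["patterns/matrix"][...], fh["patterns"].attrs["descriptor"]
        )
        frames = {}
        for name, sub in fh["frames"].items():
            seed = int(sub.attrs["seed"])
            frames[name] = MeasurementFrame(
                V=sub["V"][...],
                noise_std=float(sub.attrs["noise_std"]),
                label=str(sub.attrs["label"]),
                seed=None if seed < 0 else seed,
                noise_free=sub["noise_free"][...] if "noise_free" in sub else None,
            )
    return frames, patterns


def _parse_state(s):
    if s == HEALTHY:
        return HEALTHY
    return float(s)


def load_run_config(path) -> tuple[HeadPhantomSpec, ScenarioGrid, ExperimentConfig]:
    """Read a TOML run configuration.

    ``[phantom]`` keys map to :class:`HeadPhantomSpec` fields, ``[grid]``
    holds ``states`` (``"healthy"`` or diameters in metres), ``locations``
    and ``algorithms``, and ``[experiment]`` keys map to
    :class:`ExperimentConfig` fields (Gauss-Newton / MLSQR settings under
    ``gn_*`` / ``mlsqr_*`` prefixes).
    """
    import tomllib

    from .recon_absolute import GNSettings
    from .recon_monitoring import MLSQRSettings

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    ph = dict(raw.get("phantom", {}))
    if "layer_radii" in ph:
        ph["layer_radii"] = tuple(ph["layer_radii"])
    if "hemorrhage_diameters" in ph:
        ph["hemorrhage_diameters"] = tuple(ph["hemorrhage_diameters"])
    if "hemorrhage_center" in ph:
        ph["hemorrhage_center"] = tuple(ph["hemorrhage_center"])
    spec = HeadPhantomSpec(**ph)

    g = raw.get("grid", {})
    grid = build_grid(
        [_parse_state(s) for s in g.get("states", [HEALTHY, 0.010, 0.020, 0.030])],
        locations=g.get("locations", ["cortical"]),
        algorithms=g.get("algorithms", ["tv", "ld", "mo"]),
    )

    ex = dict(raw.get("experiment", {}))
    gn_kwargs = {k[3:]: ex.pop(k) for k in list(ex) if k.startswith("gn_")}
    ml_kwargs = {k[6:]: ex.pop(k) for k in list(ex) if k.startswith("mlsqr_")}
    cfg = ExperimentConfig(**ex)
    if gn_kwargs:
        cfg.gn = GNSettings(**{**cfg.gn.__dict__, **gn_kwargs})
    if ml_kwargs:
        cfg.mlsqr = MLSQRSettings(**{**cfg.mlsqr.__dict__, **ml_kwargs})
    return spec, grid, cfg
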