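"""File formats: multi-page TIFF volumes, 16-bit enface images, YAML
configs and CSV pair manifests.

Conventions (recorded in every volume's metadata): axis order is
(R, X, Y, Z) for repeat series and (X, Y, Z) for angiogram volumes,
with (x, y) the enface plane (x fast, y slow) and z depth; indices are
0-based.  Intensities in [0, 1] are stored as uint16 with linear
scaling, so a write/read round trip is exact to 1/65535.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .angio import AngiogramVolume, EnfaceImage, PairedSample
from .phantom import PhantomSpec, VolumeSeries

__all__ = ["write_volume", "read_volume", "write_mask", "read_mask",
           "write_enface", "read_enface", "save_config", "load_config",
           "write_manifest", "read_manifest", "save_phantom_spec",
           "load_phantom_spec"]

_SCALE = 65535.0


def _to_u16(values: np.ndarray) -> np.ndarray:
    return np.round(np.clip(values, 0.0, 1.0) * _SCALE).astype(np.uint16)


def _from_u16(values: np.ndarray) -> np.ndarray:
    return values.astype(np.float64) / _SCALE


def write_volume(vol, path) -> None:
    """Write an AngiogramVolume or VolumeSeries as a multi-page TIFF."""
    if isinstance(vol, VolumeSeries):
        meta = {"kind": "VolumeSeries", "axes": "RXYZ",
                "shape": list(vol.frames.shape),
                "n_repeats": int(vol.n_repeats),
                "sampling_ratio": int(vol.sampling_ratio),
                "spec": asdict(vol.spec)}
        data = _to_u16(vol.frames)
    elif isinstance(vol, AngiogramVolume):
        meta = {"kind": "AngiogramVolume", "axes": "XYZ",
                "shape": list(vol.values.shape),
                "n_repeats_used": int(vol.n_repeats_used),
                "sampling_ratio": int(vol.sampling_ratio)}
        data = _to_u16(vol.values)
    else:
        raise TypeError("expected AngiogramVolume or VolumeSeries")
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_volume(path, mask_path=None):
    """Read a volume written by :func:`write_volume`.

    Returns an AngiogramVolume or a VolumeSeries according to the stored
    metadata.  For a series, the ground-truth vessel mask is loaded from
    ``mask_path`` when given, otherwise an all-false mask is attached.
    """
    with tifffile.TiffFile(path) as tf:
        desc = tf.pages[0].description
        data = tf.asarray()
    try:
        meta = json.loads(desc)
        kind = meta["kind"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"{path}: missing or malformed volume metadata "
                         f"(expected JSON with a 'kind' field)") from exc
    if list(data.shape) != meta["shape"]:
        raise ValueError(f"{path}: stored shape {list(data.shape)} does not "
                         f"match declared {meta['shape']} (axes {meta['axes']})")
    values = _from_u16(data)
    if kind == "AngiogramVolume":
        return AngiogramVolume(values=values,
                               n_repeats_used=meta["n_repeats_used"],
                               sampling_ratio=meta["sampling_ratio"])
    if kind == "VolumeSeries":
        spec = PhantomSpec(**{**meta["spec"],
                              "grid_size": tuple(meta["spec"]["grid_size"]),
                              "radius_range": tuple(meta["spec"]["radius_range"])})
        mask = (read_mask(mask_path) if mask_path is not None
                else np.zeros(values.shape[1:], dtype=bool))
        return VolumeSeries(frames=values, vessel_mask=mask, spec=spec,
                            sampling_ratio=meta["sampling_ratio"])
    raise ValueError(f"{path}: unknown volume kind {kind!r}")


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=bool).astype(np.uint8),
                     description=json.dumps({"kind": "mask", "axes": "XYZ"}))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_enface(img: EnfaceImage, path) -> None:
    """16-bit enface image; .png via imageio, .tif via tifffile."""
    path = Path(path)
    data = _to_u16(img.pixels)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio
        iio.imwrite(path, data)
    else:
        tifffile.imwrite(path, data, description=json.dumps(
            {"kind": img.kind, "depth_index": img.depth_index}))


def read_enface(path, kind: str = "sectioned", depth_index=None) -> EnfaceImage:
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio
        data = iio.imread(path)
    else:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            try:
                meta = json.loads(tf.pages[0].description)
                kind = meta.get("kind", kind)
                depth_index = meta.get("depth_index", depth_index)
            except (json.JSONDecodeError, TypeError):
                pass
    return EnfaceImage(_from_u16(np.asarray(data)), kind=kind,
                       depth_index=depth_index)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_phantom_spec(spec: PhantomSpec, path) -> None:
    d = asdict(spec)
    d["grid_size"] = list(d["grid_size"])
    d["radius_range"] = list(d["radius_range"])
    save_config(d, path)


def load_phantom_spec(path) -> PhantomSpec:
    d = load_config(path)
    d["grid_size"] = tuple(d["grid_size"])
    d["radius_range"] = tuple(d["radius_range"])
    return PhantomSpec(**d)


def write_manifest(pairs: list, out_dir, split_labels=None) -> Path:
    """Write paired images plus a CSV manifest; returns the manifest path.

    One row per pair: lr_lq/hr_lq/hr_hq file paths, ratio, depth_index
    and an optional split label.
    """
    import pandas as pd
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, pair in enumerate(pairs):
        entry = {}
        for role in ("lr_lq", "hr_lq", "hr_hq"):
            p = out_dir / f"pair{i:05d}_{role}.tif"
            write_enface(getattr(pair, role), p)
            entry[role] = p.name
        entry["ratio"] = pair.ratio
        entry["depth_index"] = pair.hr_hq.depth_index
        entry["split"] = split_labels[i] if split_labels is not None else ""
        rows.append(entry)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path):
    """Load (pairs, split_labels) from a manifest CSV."""
    import pandas as pd
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, keep_default_na=False)
    base = manifest_path.parent
    pairs, labels = [], []
    for _, row in df.iterrows():
        pairs.append(PairedSample(
            lr_lq=read_enface(base / row["lr_lq"]),
            hr_lq=read_enface(base / row["hr_lq"]),
            hr_hq=read_enface(base / row["hr_hq"]),
            ratio=int(row["ratio"])))
        labels.append(str(row["split"]))
    return pairs, labels
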