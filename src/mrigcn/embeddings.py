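"""Image standardization and pluggable-backbone feature extraction.

Raw scans are converted to RGB, bilinearly resized to the backbone's
299x299 input resolution and rescaled to the backbone's input range.
The backbone itself is a contract (``BackboneContract``): any callable
mapping a batch of standardized images to fixed-width feature vectors.
Feature tables round-trip through TSV and HDF5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TARGET_SIZE = 299

CLASS_NAMES = ("glioma", "meningioma", "pituitary", "notumor")


class ChannelError(ValueError):
    """Input image does not carry exactly three channels."""


class DimensionError(ValueError):
    """Input image has a zero-sized spatial dimension."""


class BackboneContractError(ValueError):
    """Backbone output violates its declared output dimension."""


class FeatureTableError(ValueError):
    """Malformed or empty feature-table file."""


@dataclass(frozen=True)
class StandardizedImage:
    """299x299x3 RGB image on the backbone's normalized scale."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.shape != (TARGET_SIZE, TARGET_SIZE, 3):
            raise DimensionError(
                f"standardized image must be {TARGET_SIZE}x{TARGET_SIZE}x3, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("standardized image contains non-finite values")
        object.__setattr__(self, "pixels", px)


@dataclass
class EmbeddingTable:
    """N x d feature matrix with per-row identifiers and optional labels."""

    vectors: np.ndarray
    ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise FeatureTableError("vectors must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.vectors)):
            raise FeatureTableError("vectors contain NaN/Inf entries")
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != self.vectors.shape[0]:
            raise FeatureTableError("ids must align 1:1 with rows")
        if len(set(self.ids)) != len(self.ids):
            raise FeatureTableError("ids must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.vectors.shape[0],):
                raise FeatureTableError("labels must align 1:1 with rows")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class BackboneContract:
    """Pluggable feature extractor: batch of standardized images -> N x d."""

    embed: Callable[[np.ndarray], np.ndarray]
    output_dim: int

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        out = np.asarray(self.embed(batch), dtype=np.float64)
        if out.ndim != 2 or out.shape[1] != self.output_dim:
            raise BackboneContractError(
                f"backbone returned shape {out.shape}, expected (*, {self.output_dim})"
            )
        return out


def _bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resampling with half-pixel-center source coordinates."""
    in_h, in_w = img.shape[:2]
    # source coordinate of each output pixel center
    ys = (np.arange(out_h) + 0.5) * (in_h / out_h) - 0.5
    xs = (np.arange(out_w) + 0.5) * (in_w / out_w) - 0.5
    ys = np.clip(ys, 0.0, in_h - 1.0)
    xs = np.clip(xs, 0.0, in_w - 1.0)
    y0 = np.floor(ys).astype(np.intp)
    x0 = np.floor(xs).astype(np.intp)
    y1 = np.minimum(y0 + 1, in_h - 1)
    x1 = np.minimum(x0 + 1, in_w - 1)
    wy = (ys - y0)[:, None, None]
    wx = (xs - x0)[None, :, None]
    img = img.astype(np.float64)
    top = img[y0][:, x0] * (1 - wx) + img[y0][:, x1] * wx
    bot = img[y1][:, x0] * (1 - wx) + img[y1][:, x1] * wx
    return top * (1 - wy) + bot * wy


def preprocess_image(
    pixels: np.ndarray,
    channel_order: str = "BGR",
    source_id: str = "",
    normalization: str = "symmetric",
) -> StandardizedImage:
    """Standardize a raw scan: RGB order, 299x299 bilinear resize, rescale.

    Parameters
    ----------
    pixels
        H x W x 3 integer array with values in [0, 255].
    channel_order
        ``"BGR"`` (swapped to RGB) or ``"RGB"``.
    normalization
        ``"symmetric"`` maps [0, 255] linearly onto [-1, 1] (the input
        convention of the Inception backbone family); ``"mean_std"``
        applies per-channel ImageNet mean/std normalization.
    """
    px = np.asarray(pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ChannelError(f"expected H x W x 3 input, got shape {px.shape}")
    if px.shape[0] < 1 or px.shape[1] < 1:
        raise DimensionError(f"zero-sized image: shape {px.shape}")
    order = channel_order.upper()
    if order == "BGR":
        px = px[:, :, ::-1]
    elif order != "RGB":
        raise ValueError(f"unknown channel order {channel_order!r}")
    px = px.astype(np.float64)
    if px.shape[:2] != (TARGET_SIZE, TARGET_SIZE):
        px = _bilinear_resize(px, TARGET_SIZE, TARGET_SIZE)
    if normalization == "symmetric":
        px = px / 127.5 - 1.0
    elif normalization == "mean_std":
        mean = np.array([0.485, 0.456, 0.406]) * 255.0
        std = np.array([0.229, 0.224, 0.225]) * 255.0
        px = (px - mean) / std
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return StandardizedImage(pixels=px, source_id=source_id)


def extract_embeddings(
    imgs: Sequence[StandardizedImage],
    backbone: BackboneContract,
    batch_size: int = 32,
) -> EmbeddingTable:
    """Run the backbone over standardized images, skipping failures.

    Images whose pixel data raises during batching are skipped with a
    logged warning; surviving rows keep input order.
    """
    if len(imgs) == 0:
        raise FeatureTableError("no images to embed")
    kept: list[StandardizedImage] = []
    for img in imgs:
        try:
            px = np.asarray(img.pixels, dtype=np.float64)
            if px.shape != (TARGET_SIZE, TARGET_SIZE, 3) or not np.all(np.isfinite(px)):
                raise ValueError("corrupt image")
            kept.append(img)
        except Exception:
            logger.warning("skipping unreadable image %r", getattr(img, "source_id", "?"))
    if not kept:
        raise FeatureTableError("all images failed quality control")
    rows: list[np.ndarray] = []
    n_batches = (len(kept) + batch_size - 1) // batch_size
    for b in range(n_batches):
        batch = kept[b * batch_size : (b + 1) * batch_size]
        stacked = np.stack([im.pixels for im in batch])
        rows.append(backbone(stacked))
        logger.info("embedded batch %d/%d (%d images)", b + 1, n_batches, len(batch))
    vectors = np.vstack(rows)
    ids = [im.source_id or f"img_{i}" for i, im in enumerate(kept)]
    return EmbeddingTable(vectors=vectors, ids=ids)


def save_feature_table(table: EmbeddingTable, path: str | Path, format: str | None = None) -> Path:
    """Write an embedding table as TSV (id, label, v1..vd) or HDF5."""
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "tsv")
    if fmt == "tsv":
        df = pd.DataFrame(table.vectors, columns=[f"v{i+1}" for i in range(table.dim)])
        df.insert(0, "label", table.labels if table.labels is not None else -1)
        df.insert(0, "id", table.ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("vectors", data=table.vectors)
            f.create_dataset("ids", data=np.array(table.ids, dtype=h5py.string_dtype()))
            if table.labels is not None:
                f.create_dataset("labels", data=table.labels)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def load_feature_table(path: str | Path, format: str | None = None) -> EmbeddingTable:
    """Read an embedding table written by :func:`save_feature_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "tsv")
    if fmt == "tsv":
        if path.stat().st_size == 0:
            raise FeatureTableError(f"empty feature table: {path}")
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:  # pragma: no cover - pandas error paths
            raise FeatureTableError(f"unreadable TSV {path}: {exc}") from exc
        if df.empty or "id" not in df.columns:
            raise FeatureTableError(f"malformed feature table: {path}")
        vec_cols = [c for c in df.columns if c.startswith("v")]
        vectors = df[vec_cols].to_numpy()
        if vectors.dtype == object or not np.issubdtype(vectors.dtype, np.number):
            raise FeatureTableError(f"non-numeric cells in {path}")
        labels = df["label"].to_numpy(dtype=np.int64) if "label" in df.columns else None
        if labels is not None and np.all(labels < 0):
            labels = None
        return EmbeddingTable(vectors=vectors, ids=df["id"].astype(str).tolist(), labels=labels)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "vectors" not in f:
                raise FeatureTableError(f"missing 'vectors' dataset in {path}")
            vectors = f["vectors"][:]
            ids = [i.decode() if isinstance(i, bytes) else str(i) for i in f["ids"][:]]
            labels = f["labels"][:] if "labels" in f else None
        return EmbeddingTable(vectors=vectors, ids=ids, labels=labels)
    raise ValueError(f"unknown format {fmt!r}")


def load_image_directory(
    root: str | Path,
    backbone: BackboneContract,
    channel_order: str = "BGR",
    class_names: Iterable[str] = CLASS_NAMES,
) -> EmbeddingTable:
    """Embed a ``<root>/<class>/*.png`` directory tree into a labeled table."""
    from PIL import Image

    root = Path(root)
    imgs: list[StandardizedImage] = []
    labels: list[int] = []
    for ci, cname in enumerate(class_names):
        cdir = root / cname
        if not cdir.is_dir():
            continue
        for fp in sorted(cdir.iterdir()):
            if fp.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                continue
            try:
                raw = np.asarray(Image.open(fp).convert("RGB"))
                imgs.append(preprocess_image(raw, channel_order="RGB", source_id=str(fp)))
                labels.append(ci)
            except Exception:
                logger.warning("skipping unreadable file %s", fp)
    table = extract_embeddings(imgs, backbone)
    table.labels = np.asarray(labels, dtype=np.int64)
    return table
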