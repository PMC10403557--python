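"""Labeled image datasets: containers, preprocessing, splits, injection, I/O.

The canonical in-memory unit is an 8-bit grayscale raster (``numpy.uint8``,
row-major, origin top-left).  Raw detector values (e.g. DICOM) enter through
:func:`window_and_quantize`, which applies the linear window mapping and
area-weighted resize.  On disk a dataset is a directory of grayscale PNGs plus
a manifest CSV with columns ``path,label,patient_id``.

Shortcut construction follows one pattern everywhere: split a pool of
disease-free images into two equal random halves, call one half positive, and
transform exactly the positive half with one acquisition-dependent attribute
(ADA) perturbation.  The ``injected_ada`` provenance field records that a
dataset has been so transformed; double injection is forbidden.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._image import quantize_u8
from .ada import ADASpec, apply_ada


@dataclass
class LabeledDataset:
    """Images + binary labels + optional patient IDs + injection provenance."""

    images: list[np.ndarray]
    labels: np.ndarray
    patient_ids: list[str] | None = None
    injected_ada: tuple[ADASpec, int] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0 or 1, found {sorted(bad)}")
        if self.patient_ids is not None and len(self.patient_ids) != len(self.images):
            raise ValueError("patient_ids length must match images")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.labels == 0))

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError(
                f"dataset {self.name!r} needs both classes "
                f"(n_pos={self.n_pos}, n_neg={self.n_neg})"
            )


@dataclass(frozen=True)
class PreprocessSpec:
    """Window mapping + output geometry for raw-to-8-bit conversion."""

    window_center: float = 127.5
    window_width: float = 255.0
    out_size: int = 64
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError(f"window_width must be > 0, got {self.window_width}")
        if self.out_size < 8:
            raise ValueError(f"out_size must be >= 8, got {self.out_size}")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit output is supported")


def window_and_quantize(raw: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Map raw detector values through a (center, width) window to 8 bits.

    ``out = round(255 * clip((raw - (center - width/2)) / width, 0, 1))``,
    then resized to ``out_size x out_size`` by area-weighted interpolation
    (Pillow BOX resampling) and re-quantized.  Idempotent on already-8-bit
    in-range inputs under the full-range window at matching size.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2:
        raise ValueError(f"expected a 2D raster, got shape {raw.shape}")
    lo = spec.window_center - spec.window_width / 2.0
    scaled = np.clip((raw - lo) / spec.window_width, 0.0, 1.0)
    img = quantize_u8(255.0 * scaled)
    if img.shape != (spec.out_size, spec.out_size):
        resized = Image.fromarray(img.astype(np.float32), mode="F").resize(
            (spec.out_size, spec.out_size), resample=Image.Resampling.BOX
        )
        img = quantize_u8(np.asarray(resized, dtype=np.float64))
    return img


def equal_random_split(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Split indices 0..n-1 into two disjoint halves, uniformly at random.

    Returns ``(A, B)`` with ``|A| = ceil(n/2)`` and ``|B| = floor(n/2)``;
    deterministic given ``(n, seed)``.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    half = (n + 1) // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def build_detective_trainset(
    normals: list[np.ndarray], ada: ADASpec, seed: int
) -> LabeledDataset:
    """Construct a shortcut training set from a pool of disease-free images.

    An equal random split assigns labels; every positive-class image is
    transformed once by ``ada``; negatives are untouched.  Because the pool is
    disease-free, any learnable class difference is the injected attribute.
    """
    if len(normals) < 2:
        raise ValueError("need at least 2 images")
    shapes = {img.shape for img in normals}
    if len(shapes) > 1:
        raise ValueError(f"mixed image sizes: {sorted(shapes)}")
    pos_idx, _ = equal_random_split(len(normals), seed)
    pos = set(int(i) for i in pos_idx)
    images, labels = [], []
    for i, img in enumerate(normals):
        if i in pos:
            images.append(apply_ada(img, ada))
            labels.append(1)
        else:
            images.append(np.array(img, dtype=np.uint8, copy=True))
            labels.append(0)
    return LabeledDataset(
        images=images,
        labels=np.array(labels),
        injected_ada=(ada, 1),
        name=f"trainset[{ada.describe()}]",
    )


def inject_into_class(
    dataset: LabeledDataset, ada: ADASpec, target_label: int
) -> LabeledDataset:
    """Transform every image of one class; record provenance.

    Refuses to inject into a dataset that already carries an injection
    (double injection would confound the exam semantics).
    """
    if target_label not in (0, 1):
        raise ValueError(f"target_label must be 0 or 1, got {target_label}")
    if dataset.injected_ada is not None:
        raise ValueError(
            f"dataset {dataset.name!r} already carries an injection; "
            "double injection is forbidden"
        )
    dataset.require_both_classes()
    images = [
        apply_ada(img, ada) if lbl == target_label
        else np.array(img, dtype=np.uint8, copy=True)
        for img, lbl in zip(dataset.images, dataset.labels)
    ]
    return LabeledDataset(
        images=images,
        labels=dataset.labels.copy(),
        patient_ids=list(dataset.patient_ids) if dataset.patient_ids else None,
        injected_ada=(ada, target_label),
        name=f"{dataset.name}+{ada.describe()}@{target_label}",
    )


def write_manifest(dataset: LabeledDataset, root: str | Path) -> Path:
    """Write a dataset to ``root`` as PNGs plus ``manifest.csv``.

    Paths in the manifest are relative to ``root``.  Returns the manifest path.
    """
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lbl) in enumerate(zip(dataset.images, dataset.labels)):
        rel = f"images/{i:06d}.png"
        Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(root / rel)
        pid = dataset.patient_ids[i] if dataset.patient_ids else ""
        rows.append({"path": rel, "label": int(lbl), "patient_id": pid})
    manifest = root / "manifest.csv"
    pd.DataFrame(rows, columns=["path", "label", "patient_id"]).to_csv(
        manifest, index=False, quoting=csv.QUOTE_MINIMAL
    )
    if dataset.injected_ada is not None:
        ada, target = dataset.injected_ada
        (root / "provenance.json").write_text(json.dumps(
            {"ada": ada.to_dict(), "target_label": target, "name": dataset.name},
            indent=1,
        ))
    return manifest


def _load_image(path: Path, preprocess: PreprocessSpec | None) -> np.ndarray:
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        raw = ds.pixel_array.astype(np.float64)
        spec = preprocess
        if spec is None:
            # default window: DICOM attributes when present, else full range
            def _first(v):
                try:
                    return float(v)
                except TypeError:  # multi-valued window attribute
                    return float(v[0])

            center = getattr(ds, "WindowCenter", None)
            width = getattr(ds, "WindowWidth", None)
            if center is not None and width is not None:
                center, width = _first(center), _first(width)
            else:
                lo, hi = float(raw.min()), float(raw.max())
                center, width = (lo + hi) / 2.0, max(hi - lo, 1.0)
            spec = PreprocessSpec(
                window_center=center, window_width=width, out_size=raw.shape[0]
            )
        return window_and_quantize(raw, spec)
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def read_manifest(
    manifest_path: str | Path, preprocess: PreprocessSpec | None = None
) -> LabeledDataset:
    """Read a manifest CSV and load its images.

    The CSV needs a header ``path,label`` with an optional ``patient_id``
    column; paths are resolved relative to the manifest's directory.  PNG (or
    any Pillow-readable grayscale) is loaded directly; DICOM is windowed and
    quantized via ``preprocess`` (or the file's own default window attributes).
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype={"path": str, "patient_id": str})
    for col in ("path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    bad = df.index[~df["label"].astype(str).isin(["0", "1"])].tolist()
    if bad:
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"unknown label values in manifest rows: {rows}")
    root = manifest_path.parent
    missing = [p for p in df["path"] if not (root / p).is_file()]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing[:10]}")
    images = [_load_image(root / p, preprocess) for p in df["path"]]
    labels = df["label"].astype(int).to_numpy()
    if "patient_id" in df.columns and df["patient_id"].notna().any():
        patient_ids = df["patient_id"].fillna("").astype(str).tolist()
    else:
        patient_ids = None
    injected = None
    name = str(manifest_path)
    prov_path = root / "provenance.json"
    if prov_path.is_file():
        prov = json.loads(prov_path.read_text())
        injected = (ADASpec.from_dict(prov["ada"]), int(prov["target_label"]))
        name = prov.get("name", name)
    return LabeledDataset(
        images=images, labels=labels, patient_ids=patient_ids,
        injected_ada=injected, name=name,
    )
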