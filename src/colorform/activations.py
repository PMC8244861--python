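"""Adapter contract for extracting flattened activations from named layers
of any layered model, plus layer bookkeeping and an HDF5 activation cache.

Every model (pretrained framework network, random-weight network, or the
toy NumPy stack in :mod:`colorform.synth`) is wrapped in a
:class:`ModelAdapter`; downstream metrics only ever see
:class:`ActivationMatrix` objects, so they are source-agnostic.
"""

from __future__ import annotations

import importlib.util
import json
from abc import ABC, abstractmethod
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import AdapterEnvironmentError, DataIntegrityError, InputDomainError

__all__ = [
    "LayerDescriptor",
    "ActivationMatrix",
    "ModelAdapter",
    "compute_layer_fraction",
    "extract_activations",
    "random_init_adapter",
    "save_activation_cache",
    "load_activation_cache",
    "layer_table",
]


def compute_layer_fraction(position: int, total_layers: int) -> float:
    """Fraction of the network traversed: 1-based ``position / total_layers``.

    The first layer of a ten-layer network scores 0.1; the final layer 1.0.
    """
    if not 1 <= position <= total_layers:
        raise InputDomainError(
            f"position {position} outside [1, {total_layers}]"
        )
    return position / total_layers


@dataclass(frozen=True)
class LayerDescriptor:
    """Bookkeeping for one named layer in a model's forward sequence."""

    network_id: str
    layer_label: str
    position: int  # 1-based index in the full forward sequence
    total_layers: int  # every module in the forward pass
    n_units: int
    layer_class: str = "other"  # conv | relu | pool | fc | other

    @property
    def layer_fraction(self) -> float:
        return compute_layer_fraction(self.position, self.total_layers)

    @property
    def is_fully_connected(self) -> bool:
        return self.layer_class == "fc"


@dataclass
class ActivationMatrix:
    """Stimuli x units activation matrix for one layer.

    ``row_keys`` bind each row to its stimulus ``(object_id, hue_index,
    variant)`` in manifest order.
    """

    layer: LayerDescriptor
    row_keys: list[tuple]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DataIntegrityError("activation values must be 2-D")
        if self.values.shape[0] != len(self.row_keys):
            raise DataIntegrityError("row count must equal stimulus count")
        if self.values.shape[1] != self.layer.n_units:
            raise DataIntegrityError("column count must equal layer n_units")
        if not np.isfinite(self.values).all():
            raise DataIntegrityError(
                f"non-finite activations in layer {self.layer.layer_label!r}"
            )

    def rows_for(self, object_id, variant=None) -> np.ndarray:
        """Row indices of a given object (optionally restricted to a variant),
        in stored order."""
        return np.array(
            [
                i
                for i, (obj, _h, var) in enumerate(self.row_keys)
                if obj == object_id and (variant is None or var == variant)
            ]
        )

    @property
    def object_ids(self) -> list:
        seen = dict.fromkeys(obj for obj, _h, _v in self.row_keys)
        return list(seen)


class ModelAdapter(ABC):
    """Uniform interface to a layered model.

    Implementations must be deterministic in evaluation mode: the same
    input batch with the same weights yields identical activations, and
    layer enumeration is stable across calls.
    """

    network_id: str
    preprocessing: dict  # recipe recorded into manifests

    @abstractmethod
    def enumerate_layers(self) -> list[LayerDescriptor]:
        """All exposed layers, ordered by forward position."""

    @abstractmethod
    def forward(self, batch: np.ndarray, layer_labels: list[str]) -> dict:
        """Map ``layer_label -> (n_stimuli, ...) activation array`` for a
        preprocessed batch."""

    @abstractmethod
    def preprocess(self, rasters: np.ndarray) -> np.ndarray:
        """Turn (N, H, W, 3) uint8 rasters into the model's input batch."""


def extract_activations(
    adapter: ModelAdapter,
    stimuli,
    layer_labels: list[str] | None = None,
) -> dict[str, ActivationMatrix]:
    """Run a stimulus set through an adapter and collect one flattened
    ActivationMatrix per requested layer.

    Multi-dimensional layer outputs are flattened in C order
    (channel-major, then row-major over space).
    """
    descriptors = {d.layer_label: d for d in adapter.enumerate_layers()}
    if layer_labels is None:
        layer_labels = list(descriptors)
    unknown = [lab for lab in layer_labels if lab not in descriptors]
    if unknown:
        raise LookupError(
            f"unknown layers {unknown}; available: {list(descriptors)}"
        )

    if hasattr(stimuli, "images"):  # a StimulusSet
        rasters = np.stack([im.raster for im in stimuli.images])
        row_keys = [im.key for im in stimuli.images]
    else:
        rasters = np.asarray(stimuli)
        row_keys = [(f"row{i}", -1, "raw") for i in range(rasters.shape[0])]

    batch = adapter.preprocess(rasters)
    outputs = adapter.forward(batch, layer_labels)

    matrices = {}
    for label in layer_labels:
        flat = np.asarray(outputs[label]).reshape(len(row_keys), -1)
        if not np.isfinite(flat).all():
            raise DataIntegrityError(f"non-finite activation in layer {label!r}")
        matrices[label] = ActivationMatrix(descriptors[label], list(row_keys), flat)
    return matrices


def layer_table(descriptors: list[LayerDescriptor]) -> pd.DataFrame:
    """LayerDescriptor list as a tidy table (CSV-exportable)."""
    df = pd.DataFrame([asdict(d) for d in descriptors])
    df["layer_fraction"] = [d.layer_fraction for d in descriptors]
    return df


def random_init_adapter(architecture_id: str, seed: int, **kwargs) -> ModelAdapter:
    """Construct an untrained random-weight adapter.

    ``"toy"`` builds the NumPy conv stack from :mod:`colorform.synth`
    (always available); any torchvision architecture name requires torch
    to be installed.
    """
    if architecture_id == "toy":
        from .synth import toy_network_adapter

        return toy_network_adapter(seed=seed, **kwargs)
    if importlib.util.find_spec("torch") is None:
        raise AdapterEnvironmentError(
            f"architecture {architecture_id!r} requires torch/torchvision, "
            "which are not installed; the 'toy' architecture needs no framework"
        )
    from .torch_adapter import TorchvisionAdapter

    return TorchvisionAdapter(architecture_id, weights=None, seed=seed, **kwargs)


# --------------------------------------------------------------------------
# HDF5 cache


def save_activation_cache(path, matrices: dict[str, ActivationMatrix], manifest=None):
    """Persist activation matrices (one dataset per layer) with their
    descriptors and row keys; optionally embed the stimulus manifest."""
    import h5py

    with h5py.File(path, "w") as f:
        for label, mat in matrices.items():
            grp = f.create_group(f"layers/{label}")
            grp.create_dataset("values", data=mat.values)
            grp.attrs["descriptor"] = json.dumps(asdict(mat.layer))
            grp.attrs["row_keys"] = json.dumps(
                [[str(o), int(h), str(v)] for o, h, v in mat.row_keys]
            )
        if manifest is not None:
            f.attrs["manifest"] = manifest.to_csv(index=False)


def load_activation_cache(path):
    """Inverse of :func:`save_activation_cache`.

    Returns ``(matrices, manifest_or_None)``; round-trips bitwise.
    """
    import io

    import h5py

    matrices = {}
    manifest = None
    with h5py.File(path, "r") as f:
        for label in f["layers"]:
            grp = f[f"layers/{label}"]
            desc = LayerDescriptor(**json.loads(grp.attrs["descriptor"]))
            keys = [tuple([o, int(h), v]) for o, h, v in json.loads(grp.attrs["row_keys"])]
            matrices[label] = ActivationMatrix(desc, keys, grp["values"][()])
        if "manifest" in f.attrs:
            manifest = pd.read_csv(
                io.StringIO(f.attrs["manifest"]), float_precision="round_trip"
            )
    return matrices, manifest
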