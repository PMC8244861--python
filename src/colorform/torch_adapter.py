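"""Optional torchvision-backed adapter (requires torch + torchvision).

This module is imported lazily; environments without torch can use every
other part of the package (including the toy NumPy network) unaffected.
"""

from __future__ import annotations

import numpy as np

from .activations import LayerDescriptor, ModelAdapter
from .errors import AdapterEnvironmentError

_CLASS_TAGS = {
    "Conv2d": "conv",
    "ReLU": "relu",
    "MaxPool2d": "pool",
    "AvgPool2d": "pool",
    "AdaptiveAvgPool2d": "pool",
    "Linear": "fc",
}

# ImageNet normalization used by all torchvision classification models.
_MEAN = np.array([0.485, 0.456, 0.406])
_STD = np.array([0.229, 0.224, 0.225])


class TorchvisionAdapter(ModelAdapter):
    """Wraps a torchvision classification model, exposing every leaf module
    (in forward-execution order, discovered with a probe pass) as a layer."""

    def __init__(self, architecture_id: str, weights=None, seed: int | None = None,
                 input_size: int = 224):
        try:
            import torch
            import torchvision.models as tvm
        except ImportError as exc:  # pragma: no cover - depends on environment
            raise AdapterEnvironmentError(
                "torch/torchvision are required for pretrained architectures"
            ) from exc

        self._torch = torch
        if seed is not None:
            torch.manual_seed(seed)
        factory = getattr(tvm, architecture_id, None)
        if factory is None:
            raise AdapterEnvironmentError(f"unknown torchvision model {architecture_id!r}")
        self.model = factory(weights=weights).eval()
        self.network_id = f"{architecture_id}({'pretrained' if weights else f'random:{seed}'})"
        self.input_size = input_size
        self.preprocessing = {
            "resize": [input_size, input_size],
            "normalize_mean": _MEAN.tolist(),
            "normalize_std": _STD.tolist(),
            "layout": "NCHW",
        }
        self._order = self._discover_forward_order()

    def _leaf_modules(self):
        return [
            (name, mod)
            for name, mod in self.model.named_modules()
            if name and not list(mod.children())
        ]

    def _discover_forward_order(self):
        """Order leaf modules by actual execution via forward hooks on a
        probe input (handles recurrent/reused modules by first call)."""
        torch = self._torch
        order: list[str] = []
        handles = []
        for name, mod in self._leaf_modules():
            def hook(_m, _i, _o, name=name):
                if name not in order:
                    order.append(name)
            handles.append(mod.register_forward_hook(hook))
        with torch.no_grad():
            self.model(torch.zeros(1, 3, self.input_size, self.input_size))
        for h in handles:
            h.remove()
        return order

    def enumerate_layers(self):
        torch = self._torch
        shapes = {}
        mods = dict(self._leaf_modules())
        handles = []
        for name in self._order:
            def hook(_m, _i, out, name=name):
                if name not in shapes and hasattr(out, "shape"):
                    shapes[name] = tuple(out.shape[1:])
            handles.append(mods[name].register_forward_hook(hook))
        with torch.no_grad():
            self.model(torch.zeros(1, 3, self.input_size, self.input_size))
        for h in handles:
            h.remove()
        total = len(self._order)
        return [
            LayerDescriptor(
                network_id=self.network_id,
                layer_label=name,
                position=pos,
                total_layers=total,
                n_units=int(np.prod(shapes.get(name, (1,)))),
                layer_class=_CLASS_TAGS.get(type(mods[name]).__name__, "other"),
            )
            for pos, name in enumerate(self._order, start=1)
        ]

    def preprocess(self, rasters: np.ndarray) -> np.ndarray:
        from PIL import Image

        size = self.input_size
        resized = np.stack(
            [
                np.asarray(
                    Image.fromarray(r.astype(np.uint8)).resize((size, size), Image.BILINEAR),
                    dtype=np.float64,
                )
                for r in np.asarray(rasters)
            ]
        )
        normed = (resized / 255.0 - _MEAN) / _STD
        return normed.transpose(0, 3, 1, 2).astype(np.float32)

    def forward(self, batch: np.ndarray, layer_labels: list[str]) -> dict:
        torch = self._torch
        mods = dict(self._leaf_modules())
        unknown = [lab for lab in layer_labels if lab not in mods]
        if unknown:
            raise LookupError(f"unknown layers {unknown}; available: {self._order}")
        captured: dict[str, np.ndarray] = {}
        handles = []
        for name in layer_labels:
            def hook(_m, _i, out, name=name):
                if name not in captured:
                    captured[name] = out.detach().cpu().numpy()
            handles.append(mods[name].register_forward_hook(hook))
        with torch.no_grad():
            self.model(torch.as_tensor(batch))
        for h in handles:
            h.remove()
        return captured
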