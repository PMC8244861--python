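"""Ground-truth synthetic data: seeded unit populations mixing additive
(orthogonal) and interactive color/form tuning at a controllable strength
``lam``, and a small NumPy convolutional stack exposed through the standard
adapter contract.

Unit response model (population generator)
------------------------------------------
For unit u, color c (hue angle theta_c) and form f:

    r_u(c, f) = (1 - lam) * [alpha_u * cos(theta_c - phi_u) + beta_u * xi_{u,f}]
                + lam * gamma_{u,c,f} + eps

with alpha, beta, xi, gamma drawn i.i.d. from centered Gaussians of sd
``tuning_sd``, phi uniform on [0, 360), and eps Gaussian of sd ``noise_sd``.
At lam = 0 every form shares the same expected hue-distance geometry
(cosine color tuning), i.e. perfectly orthogonal color/form coding; at
lam = 1 tuning is independent per (color, form), the maximally interactive
reference point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .activations import ActivationMatrix, LayerDescriptor, ModelAdapter
from .errors import InputDomainError

__all__ = [
    "PopulationSpec",
    "TrajectorySpec",
    "generate_population",
    "generate_trajectory",
    "ToyConvNetAdapter",
    "toy_network_adapter",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Generative recipe for one synthetic unit population."""

    n_units: int
    n_objects: int
    lam: float  # interaction strength in [0, 1]
    n_colors: int = 12
    tuning_sd: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    noise_seed: int | None = None  # separate stream so layers can share tuning

    def __post_init__(self):
        if self.n_units < 2:
            raise InputDomainError("n_units must be >= 2")
        if not 0.0 <= self.lam <= 1.0:
            raise InputDomainError("lam must lie in [0, 1]")
        if self.tuning_sd <= 0 or self.noise_sd < 0:
            raise InputDomainError("tuning_sd must be > 0 and noise_sd >= 0")


def generate_population(spec: PopulationSpec):
    """Draw one population; returns ``(ActivationMatrix, ground_truth)``.

    Rows are ordered object-major: (obj0, color0..11), (obj1, ...), each
    keyed ``(object_id, color_index, "synthetic")``. Fully seeded: equal
    specs yield bitwise-identical matrices.
    """
    rng = np.random.default_rng(spec.seed)
    u, c, f = spec.n_units, spec.n_colors, spec.n_objects
    sd = spec.tuning_sd

    alpha = rng.normal(0.0, sd, size=u)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=u)
    beta = rng.normal(0.0, sd, size=u)
    xi = rng.normal(0.0, sd, size=(f, u))
    gamma = rng.normal(0.0, sd, size=(f, c, u))
    theta = 2.0 * np.pi * np.arange(c) / c

    additive = alpha * np.cos(theta[:, None] - phi) + beta * xi[:, None, :]
    resp = (1.0 - spec.lam) * additive + spec.lam * gamma
    if spec.noise_sd > 0:
        noise_rng = (
            rng if spec.noise_seed is None else np.random.default_rng(spec.noise_seed)
        )
        resp = resp + noise_rng.normal(0.0, spec.noise_sd, size=resp.shape)

    keys = [
        (f"obj{i:03d}", color, "synthetic") for i in range(f) for color in range(c)
    ]
    layer = LayerDescriptor(
        network_id=f"population(seed={spec.seed})",
        layer_label="population",
        position=1,
        total_layers=1,
        n_units=u,
    )
    matrix = ActivationMatrix(layer, keys, resp.reshape(f * c, u))
    return matrix, {"lam": spec.lam, "spec": spec}


@dataclass(frozen=True)
class TrajectorySpec:
    """A layered sequence of populations with a shared object/color grid and
    a per-layer interaction-strength schedule (stands in for a hierarchy)."""

    layers: tuple  # of (layer_label, PopulationSpec)

    def __post_init__(self):
        labels = [lab for lab, _ in self.layers]
        if len(set(labels)) != len(labels):
            raise InputDomainError("layer labels must be unique")
        shapes = {(s.n_objects, s.n_colors) for _, s in self.layers}
        if len(shapes) != 1:
            raise InputDomainError("all layers must share n_objects and n_colors")

    @staticmethod
    def from_schedule(
        lambdas,
        n_units: int,
        n_objects: int,
        seed: int,
        tuning_sd: float = 1.0,
        noise_sd: float = 0.0,
        n_colors: int = 12,
        shared_tuning: bool = True,
    ) -> "TrajectorySpec":
        """Build a trajectory from a lambda schedule; per-layer seeds are
        spawned deterministically from the master seed.

        With ``shared_tuning`` (the default) all layers share one draw of the
        tuning parameters and differ only in lambda and in fresh per-layer
        noise -- the analogue of one network whose entanglement grows with
        depth. With ``shared_tuning=False`` every layer is an independent
        population; layer-level sampling fluctuations are then common to all
        object pairs within a layer, which the across-pairs slope t-test
        (which assumes exchangeable pairs) does not absorb.
        """
        ss = np.random.SeedSequence(seed)
        children = [int(s.generate_state(1)[0]) for s in ss.spawn(len(lambdas) + 1)]
        base_seed, layer_seeds = children[0], children[1:]
        layers = tuple(
            (
                f"L{i + 1}",
                PopulationSpec(
                    n_units=n_units,
                    n_objects=n_objects,
                    lam=float(lam),
                    n_colors=n_colors,
                    tuning_sd=tuning_sd,
                    noise_sd=noise_sd,
                    seed=base_seed if shared_tuning else layer_seeds[i],
                    noise_seed=layer_seeds[i] if shared_tuning else None,
                ),
            )
            for i, lam in enumerate(lambdas)
        )
        return TrajectorySpec(layers)


def generate_trajectory(spec: TrajectorySpec):
    """One ActivationMatrix per layer plus the ground-truth lambda schedule.

    Layers carry positions 1..n so downstream layer_fraction regressions
    work unchanged on synthetic data.
    """
    total = len(spec.layers)
    matrices = {}
    schedule = {}
    for pos, (label, pop_spec) in enumerate(spec.layers, start=1):
        mat, truth = generate_population(pop_spec)
        layer = LayerDescriptor(
            network_id="synthetic_trajectory",
            layer_label=label,
            position=pos,
            total_layers=total,
            n_units=pop_spec.n_units,
        )
        matrices[label] = ActivationMatrix(layer, mat.row_keys, mat.values)
        schedule[label] = truth["lam"]
    return matrices, schedule


# --------------------------------------------------------------------------
# Toy convolutional network (pure NumPy)


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'Same'-padded 2-D convolution; x (N, C, H, W), w (O, C, k, k)."""
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    return np.einsum("nchwij,ocij->nohw", win, w, optimize=True)


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2).mean(axis=(3, 5))


class ToyConvNetAdapter(ModelAdapter):
    """A seeded stack of conv -> relu -> avgpool stages plus a final global
    spatial average, exposing every module as a named layer.

    Deterministic, framework-free, and fast enough to push a few hundred
    stimuli through on one CPU -- the desk-scale stand-in for a real
    pretrained hierarchy.
    """

    def __init__(
        self,
        seed: int = 0,
        n_stages: int = 5,
        channels: int = 8,
        input_size: int = 64,
        kernel: int = 3,
    ):
        if n_stages < 2:
            raise InputDomainError("n_stages must be >= 2")
        self.seed = int(seed)
        self.n_stages = n_stages
        self.channels = channels
        self.input_size = input_size
        self.kernel = kernel
        self.network_id = f"toy(seed={seed},stages={n_stages})"
        self.preprocessing = {
            "resize": [input_size, input_size],
            "scale": "1/255",
            "layout": "NCHW",
        }
        rng = np.random.default_rng(seed)
        self.weights = []
        c_in = 3
        for _ in range(n_stages):
            fan_in = c_in * kernel * kernel
            self.weights.append(
                rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(channels, c_in, kernel, kernel))
            )
            c_in = channels

    def _layer_plan(self):
        """(label, class, n_units) for every module in forward order."""
        plan = []
        size = self.input_size
        for i in range(1, self.n_stages + 1):
            plan.append((f"conv{i}", "conv", self.channels * size * size))
            plan.append((f"relu{i}", "relu", self.channels * size * size))
            size = size // 2
            plan.append((f"pool{i}", "pool", self.channels * size * size))
        plan.append(("avgpool", "pool", self.channels))
        return plan

    def enumerate_layers(self):
        plan = self._layer_plan()
        total = len(plan)
        return [
            LayerDescriptor(
                network_id=self.network_id,
                layer_label=label,
                position=pos,
                total_layers=total,
                n_units=n_units,
                layer_class=cls,
            )
            for pos, (label, cls, n_units) in enumerate(plan, start=1)
        ]

    def preprocess(self, rasters: np.ndarray) -> np.ndarray:
        from PIL import Image

        rasters = np.asarray(rasters)
        size = self.input_size
        resized = np.stack(
            [
                np.asarray(
                    Image.fromarray(r.astype(np.uint8)).resize(
                        (size, size), Image.BILINEAR
                    ),
                    dtype=np.float64,
                )
                for r in rasters
            ]
        )
        return (resized / 255.0).transpose(0, 3, 1, 2)

    def forward(self, batch: np.ndarray, layer_labels: list[str]) -> dict:
        wanted = set(layer_labels)
        out = {}
        x = np.asarray(batch, dtype=np.float64)
        for i in range(1, self.n_stages + 1):
            x = _conv_same(x, self.weights[i - 1])
            if f"conv{i}" in wanted:
                out[f"conv{i}"] = x.copy()
            x = np.maximum(x, 0.0)
            if f"relu{i}" in wanted:
                out[f"relu{i}"] = x.copy()
            x = _avgpool2(x)
            if f"pool{i}" in wanted:
                out[f"pool{i}"] = x.copy()
        if "avgpool" in wanted:
            out["avgpool"] = x.mean(axis=(2, 3))
        missing = wanted - set(out)
        if missing:
            raise LookupError(f"unknown layers {sorted(missing)}")
        return out


def toy_network_adapter(seed: int, n_stages: int = 5, **kwargs) -> ToyConvNetAdapter:
    """Seeded toy network; equal seeds yield identical weights and
    therefore identical activations on any batch."""
    return ToyConvNetAdapter(seed=seed, n_stages=n_stages, **kwargs)
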