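"""Stage orchestration: stimuli -> activation extraction -> metrics ->
inference -> report, with deterministic, cache-friendly outputs.

Every stage is a plain function over in-memory objects so it is equally
usable from the CLI, tests, and notebooks. All tables are emitted with a
fixed float format so reruns from the same config/seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, stats, stimuli as stim
from .activations import (
    ActivationMatrix,
    extract_activations,
    layer_table,
    load_activation_cache,
    random_init_adapter,
    save_activation_cache,
)
from .errors import InputDomainError
from .synth import TrajectorySpec, generate_trajectory

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "run_stimulus_stage",
    "run_extraction_stage",
    "run_analysis_stage",
    "run_simulation_stage",
    "render_report",
    "analyze_matrices",
]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Structured run configuration; hashable for provenance stamping."""

    stimulus_source: str = "builtin_bars"  # builtin_bars | image_dir:<path>
    colorspace: str = "cieluv"
    target_mean_lum: float = 60.0
    target_mean_sat: float = 40.0
    variants: tuple = ("textured",)
    network: str = "toy"
    network_seed: int = 0
    n_stages: int = 5
    layers: str = "all"
    metric: str = "pearson"
    n_shuffles: int = 100
    seed: int = 0
    n_hues: int = 12
    n_orientations: int = 12
    bar_length_px: int = 300
    bar_width_px: int = 60
    bar_canvas_px: int = 400
    toy_input_size: int = 64

    @property
    def calibration(self) -> stim.CalibrationTarget:
        return stim.CalibrationTarget(
            self.colorspace, self.target_mean_lum, self.target_mean_sat
        )

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["variants"] = list(self.variants)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if "variants" in data:
            data["variants"] = tuple(data["variants"])
        return cls(**data)


@dataclass
class AnalysisReport:
    """Tables plus test results plus provenance, regenerable bit-identically."""

    tables: dict = field(default_factory=dict)  # name -> DataFrame
    stats: dict = field(default_factory=dict)  # JSON-serializable summaries
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> str:
        """Write CSV tables + summary.json; returns a content hash."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        digest = hashlib.sha256()
        for name in sorted(self.tables):
            path = out / f"{name}.csv"
            self.tables[name].to_csv(path, index=False, float_format=_FLOAT_FMT)
            digest.update(path.read_bytes())
        summary = {"stats": self.stats, "provenance": self.provenance}
        blob = json.dumps(summary, sort_keys=True, indent=2, default=float)
        (out / "summary.json").write_text(blob)
        digest.update(blob.encode())
        return digest.hexdigest()


def run_stimulus_stage(config: RunConfig, out_dir=None) -> stim.StimulusSet:
    """Build (and optionally write) the stimulus set named by the config."""
    if config.stimulus_source == "builtin_bars":
        stimulus_set = stim.make_bars(
            config.calibration,
            n_orientations=config.n_orientations,
            n_hues=config.n_hues,
            template=stim.BarSpec(
                0.0, config.bar_length_px, config.bar_width_px, config.bar_canvas_px
            ),
        )
    elif config.stimulus_source.startswith("image_dir:"):
        directory = Path(config.stimulus_source.split(":", 1)[1])
        if not directory.is_dir():
            raise FileNotFoundError(f"stimulus image directory {directory} not found")
        stimulus_set = _stimuli_from_directory(directory, config)
    else:
        raise InputDomainError(f"unknown stimulus source {config.stimulus_source!r}")
    if out_dir is not None:
        stimulus_set.write(out_dir)
    return stimulus_set


def _stimuli_from_directory(directory: Path, config: RunConfig) -> stim.StimulusSet:
    from PIL import Image

    images = []
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    for path in paths:
        raster = np.asarray(Image.open(path).convert("RGB"))
        source = stim.SourceObjectImage(path.stem, raster)
        if "textured" in config.variants:
            images.extend(
                stim.calibrate_and_recolor(source, config.calibration, config.n_hues)
            )
        if "silhouette" in config.variants:
            images.extend(
                stim.make_silhouette(source, h, config.calibration, config.n_hues)
                for h in range(config.n_hues)
            )
        if "grayscale" in config.variants:
            images.append(stim.make_grayscale(source, config.calibration))
    return stim.StimulusSet(images)


def run_extraction_stage(
    config: RunConfig, stimulus_set: stim.StimulusSet, cache_path=None
) -> dict[str, ActivationMatrix]:
    """Push stimuli through the configured network adapter."""
    kwargs = {"input_size": config.toy_input_size} if config.network == "toy" else {}
    adapter = random_init_adapter(
        config.network, seed=config.network_seed, n_stages=config.n_stages, **kwargs
    )
    labels = None if config.layers == "all" else config.layers.split(",")
    matrices = extract_activations(adapter, stimulus_set, labels)
    if cache_path is not None:
        save_activation_cache(cache_path, matrices, stimulus_set.manifest)
    return matrices


def _sorted_layers(matrices: dict[str, ActivationMatrix]):
    return sorted(matrices.values(), key=lambda m: m.layer.position)


def analyze_matrices(
    matrices: dict[str, ActivationMatrix],
    metric: str = "pearson",
    n_shuffles: int = 0,
    seed: int = 0,
    variant: str | None = None,
    ground_truth: dict | None = None,
) -> AnalysisReport:
    """The full second-order analysis battery on a layer-keyed activation
    cache.

    Trajectory statistics (pair slopes, cross-layer regressions) use the
    first through penultimate layers; the final layer is reported in the
    tables but excluded from slope fits.
    """
    ordered = _sorted_layers(matrices)
    if len(ordered) < 1:
        raise InputDomainError("need at least one layer")

    vectors_per_layer: dict[str, dict] = {}
    rows_between, rows_within, rows_pairs = [], [], []
    cs_sim_vectors: dict[str, np.ndarray] = {}

    for mat in ordered:
        label = mat.layer.layer_label
        vecs = metrics.object_color_space_vectors(mat, metric=metric, variant=variant)
        vectors_per_layer[label] = vecs
        stacked = np.stack(list(vecs.values()))
        sim = metrics.pairwise_vector_correlation_matrix(stacked, list(vecs))
        rows_between.append(
            {
                "layer": label,
                "layer_fraction": mat.layer.layer_fraction,
                "layer_class": mat.layer.layer_class,
                "mean_between_object_r": sim.mean_offdiag,
                "ground_truth_lam": (ground_truth or {}).get(label, np.nan),
            }
        )
        objs = list(vecs)
        iu = np.triu_indices(len(objs), 1)
        for a, b, r in zip(iu[0], iu[1], sim.offdiag_vector):
            rows_pairs.append(
                {
                    "layer": label,
                    "layer_fraction": mat.layer.layer_fraction,
                    "object_a": objs[a],
                    "object_b": objs[b],
                    "r": r,
                }
            )
        if len(objs) >= 3:
            cs_sim_vectors[label] = sim.offdiag_vector
        for obj in vecs:
            idx = [
                i
                for i, (o, h, v) in enumerate(mat.row_keys)
                if o == obj and h >= 0 and (variant is None or v == variant)
            ]
            rows_within.append(
                {
                    "layer": label,
                    "layer_fraction": mat.layer.layer_fraction,
                    "object_id": obj,
                    "normalized_color_distance": metrics.within_object_color_distance(
                        mat.values[idx]
                    ),
                }
            )

    report = AnalysisReport()
    report.tables["between_object_mean"] = pd.DataFrame(rows_between)
    report.tables["between_object_pairs"] = pd.DataFrame(rows_pairs)
    report.tables["within_object_distance"] = pd.DataFrame(rows_within)

    # Pair slopes over first..penultimate layers
    if len(ordered) >= 3:
        fit_layers = ordered[:-1]
        fit_labels = [m.layer.layer_label for m in fit_layers]
        fractions = np.array([m.layer.layer_fraction for m in fit_layers])
        pairs_df = report.tables["between_object_pairs"]
        sub = pairs_df[pairs_df["layer"].isin(fit_labels)]
        slope_rows = []
        for (a, b), grp in sub.groupby(["object_a", "object_b"], sort=True):
            grp = grp.sort_values("layer_fraction")
            res = stats.pair_slope(grp["r"].to_numpy(), grp["layer_fraction"].to_numpy(), (a, b))
            slope_rows.append(
                {"object_a": a, "object_b": b, "slope": res.slope, "intercept": res.intercept}
            )
        slopes_df = pd.DataFrame(slope_rows)
        report.tables["pair_slopes"] = slopes_df
        try:
            test = stats.one_sample_t(slopes_df["slope"].to_numpy())
            report.stats["pair_slope_test"] = {
                "mean_slope": float(slopes_df["slope"].mean()),
                "t": test.t,
                "df": test.df,
                "p": test.p,
                "tier": stats.significance_tier(test.p),
                "fit_layers": fit_labels,
            }
        except Exception as exc:  # degenerate variance on toy inputs
            report.stats["pair_slope_test"] = {"error": str(exc)}

    # Cross-layer profiles (within-object), references: first and penultimate
    if len(ordered) >= 2:
        labels = [m.layer.layer_label for m in ordered]
        refs = {"first": labels[0], "penultimate": labels[-2] if len(labels) >= 2 else labels[0]}
        rows_xlayer = []
        objects = list(vectors_per_layer[labels[0]])
        for ref_name, ref_label in refs.items():
            for obj in objects:
                per_layer = {
                    lab: vectors_per_layer[lab][obj]
                    for lab in labels
                    if obj in vectors_per_layer[lab]
                }
                prof = metrics.cross_layer_profile(per_layer, ref_label)
                for lab in labels:
                    rows_xlayer.append(
                        {
                            "reference": ref_name,
                            "reference_layer": ref_label,
                            "layer": lab,
                            "layer_fraction": matrices[lab].layer.layer_fraction,
                            "object_id": obj,
                            "r": prof[lab],
                        }
                    )
        report.tables["cross_layer_profile"] = pd.DataFrame(rows_xlayer)

        # Color-space-similarity transformation across layers
        if cs_sim_vectors:
            rows_cst = []
            for ref_name, ref_label in refs.items():
                if ref_label not in cs_sim_vectors:
                    continue
                for lab, vec in cs_sim_vectors.items():
                    try:
                        r = metrics.pearson(cs_sim_vectors[ref_label], vec)
                    except Exception:
                        r = np.nan
                    rows_cst.append(
                        {
                            "reference": ref_name,
                            "reference_layer": ref_label,
                            "layer": lab,
                            "layer_fraction": matrices[lab].layer.layer_fraction,
                            "r": r,
                        }
                    )
            report.tables["colorspace_similarity_transform"] = pd.DataFrame(rows_cst)

    # Form similarity vs color-space similarity (needs grayscale rows)
    rows_form = []
    for mat in ordered:
        label = mat.layer.layer_label
        gray_idx = [
            i for i, (_o, h, v) in enumerate(mat.row_keys) if v == "grayscale" or h == -1
        ]
        if len(gray_idx) >= 3 and label in cs_sim_vectors:
            form_vec = metrics.form_similarity_vector(mat.values[gray_idx])
            try:
                r = metrics.form_vs_colorspace_correlation(form_vec, cs_sim_vectors[label])
            except Exception:
                r = np.nan
            rows_form.append(
                {"layer": label, "layer_fraction": mat.layer.layer_fraction, "r": r}
            )
    if rows_form:
        report.tables["form_vs_colorspace"] = pd.DataFrame(rows_form)

    # Shuffle null per layer
    if n_shuffles > 0:
        rows_null = []
        for mat in ordered:
            label = mat.layer.layer_label
            patterns = {}
            for obj in mat.object_ids:
                idx = [
                    i
                    for i, (o, h, v) in enumerate(mat.row_keys)
                    if o == obj and h >= 0 and (variant is None or v == variant)
                ]
                if len(idx) >= 2:
                    patterns[obj] = mat.values[idx]
            null = stats.shuffle_color_null(
                patterns, n_shuffles=n_shuffles, seed=seed, layer=label
            )
            rows_null.append(
                {
                    "layer": label,
                    "layer_fraction": mat.layer.layer_fraction,
                    "n_shuffles": n_shuffles,
                    "mean_null": null.mean_null,
                    "se_null": null.se_null,
                }
            )
        report.tables["shuffle_null"] = pd.DataFrame(rows_null)

    report.tables["layers"] = layer_table([m.layer for m in ordered])
    return report


def run_analysis_stage(
    config: RunConfig, matrices: dict[str, ActivationMatrix], out_dir=None
) -> AnalysisReport:
    report = analyze_matrices(
        matrices,
        metric=config.metric,
        n_shuffles=config.n_shuffles,
        seed=config.seed,
    )
    report.provenance = {"config": config.to_dict(), "config_hash": config.config_hash}
    if out_dir is not None:
        report.write(out_dir)
    return report


def run_simulation_stage(
    lambdas=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_units: int = 4000,
    n_objects: int = 20,
    n_seeds: int = 10,
    noise_sd: float = 0.0,
    seed: int = 0,
    trajectory_lambdas=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    out_dir=None,
) -> AnalysisReport:
    """Validation harness: the metric/stat suite on synthetic populations
    with the ground-truth interaction strength joined in."""
    from .synth import PopulationSpec, generate_population

    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_seeds)]
    for lam in lambdas:
        for s in seeds:
            mat, _ = generate_population(
                PopulationSpec(
                    n_units=n_units, n_objects=n_objects, lam=float(lam),
                    noise_sd=noise_sd, seed=s,
                )
            )
            rows.append(
                {
                    "lam": float(lam),
                    "seed": s,
                    "mean_between_object_r": metrics.between_object_mean_correlation(mat),
                }
            )
    grid_df = pd.DataFrame(rows)
    summary = (
        grid_df.groupby("lam", sort=True)["mean_between_object_r"].mean().reset_index()
    )
    monotone = bool(np.all(np.diff(summary["mean_between_object_r"]) < 0))

    traj_spec = TrajectorySpec.from_schedule(
        trajectory_lambdas, n_units=n_units, n_objects=n_objects,
        seed=seed, noise_sd=noise_sd,
    )
    traj_matrices, schedule = generate_trajectory(traj_spec)
    report = analyze_matrices(traj_matrices, ground_truth=schedule)
    report.tables["lambda_grid"] = grid_df
    report.tables["lambda_grid_summary"] = summary
    report.stats["lambda_monotone_decreasing"] = monotone
    report.provenance = {
        "seed": seed,
        "lambdas": list(map(float, lambdas)),
        "trajectory_lambdas": list(map(float, trajectory_lambdas)),
        "n_units": n_units,
        "n_objects": n_objects,
        "n_seeds": n_seeds,
    }
    if out_dir is not None:
        report.write(out_dir)
    return report


def render_report(report: AnalysisReport, out_dir, make_figures: bool = True) -> Path:
    """Human-readable bundle: markdown summary embedding line-plot figures
    (hollow markers for fully-connected layers, solid otherwise)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    figures = []
    if make_figures:
        figures = _figures(report, out)

    lines = ["# Analysis report", ""]
    prov = json.dumps(report.provenance, sort_keys=True, indent=2, default=float)
    lines += ["## Provenance", "```json", prov, "```", ""]
    for name, payload in sorted(report.stats.items()):
        lines += [f"## {name}", "```json", json.dumps(payload, sort_keys=True, indent=2, default=float), "```", ""]
    for name in sorted(report.tables):
        lines += [f"## Table: {name}", "", report.tables[name].head(20).to_markdown(index=False), ""]
    for fig in figures:
        lines += [f"![{fig.stem}]({fig.name})", ""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path


def _figures(report: AnalysisReport, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    spec = [
        ("between_object_mean", "mean_between_object_r", "Mean between-object color-space r"),
        ("shuffle_null", "mean_null", "Shuffle-null mean r"),
    ]
    for table, column, title in spec:
        if table not in report.tables:
            continue
        df = report.tables[table]
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(df["layer_fraction"], df[column], "-", color="maroon", zorder=1)
        classes = df.get("layer_class", pd.Series(["other"] * len(df)))
        for x, y, cls in zip(df["layer_fraction"], df[column], classes):
            filled = cls != "fc"
            ax.plot(
                x, y, "o",
                markerfacecolor="maroon" if filled else "white",
                markeredgecolor="maroon", zorder=2,
            )
        ax.set_xlabel("layer_fraction")
        ax.set_ylabel(column)
        ax.set_title(title)
        fig.tight_layout()
        path = out / f"fig_{table}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        made.append(path)
    return made


def reload_and_analyze(config: RunConfig, cache_path, out_dir=None) -> AnalysisReport:
    """Stage isolation: regenerate the analysis report from a cache alone."""
    matrices, _manifest = load_activation_cache(cache_path)
    return run_analysis_stage(config, matrices, out_dir=out_dir)
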