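"""End-to-end synthetic paired study: 7 subjects x 2 kidneys, alternating
side assignment, full per-kidney pipeline, paired comparison, report.

Each subject contributes one kidney per technique. Side assignment
alternates by subject parity: odd-numbered subjects (1-based) get the
pulsed technique on the left kidney and continuous on the right; even
subjects the reverse. Per-kidney randomness is a deterministic child seed,
``seed + subject_index * 10 + side_index``, so a study is fully
reproducible from its config and the paired design never shares draws
between arms.

Delivery-to-stasis is emulated by the Poisson particle-count draw and a
uniform embolic-volume draw over the regime's range; no hemodynamic
endpoint is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pairedstats import PairedSample, TestResult, median_and_range, paired_t_test, wilcoxon_signed_rank
from .phantom import (
    CONTINUOUS,
    PULSED,
    PhantomSpec,
    RegimeSpec,
    ellipsoid_volume_ml,
    simulate_kidney,
)
from .quantify import KidneyQuantification, quantify_kidney
from .segmentation import SegmentationParams, segment_particles
from .volio import write_results

__all__ = [
    "StudyConfig",
    "PairedStudyResult",
    "assign_sides",
    "run_study",
    "scaled_study_config",
    "load_study_config",
]


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to simulate and analyze one paired study.

    Kidney semi-axes are drawn uniformly per kidney from
    ``semi_axes_mm_ranges`` ((low, high) per axis); the defaults span
    ellipsoid volumes of roughly 50-130 ml, the reported organ-size range.
    ``threshold`` defaults to midway between background and particle
    intensity.
    """

    n_subjects: int = 7
    depths_px: tuple[int, ...] = (50, 100)
    continuous: RegimeSpec = CONTINUOUS
    pulsed: RegimeSpec = PULSED
    spacing_mm: float = 0.1
    semi_axes_mm_ranges: tuple[tuple[float, float], ...] = (
        (30.0, 43.0),
        (22.0, 29.0),
        (18.0, 25.0),
    )
    particle_radius_um_range: tuple[float, float] = (75.0, 100.0)
    noise_sigma: float = 50.0
    background_intensity: float = 100.0
    particle_intensity: float = 600.0
    threshold: float | None = None
    min_component_voxels: int = 1
    connectivity: int = 26
    percent_denominator: str = "shell"
    kidney_volume_source: str = "mask"  # or "ellipsoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.kidney_volume_source not in ("mask", "ellipsoid"):
            raise ValueError("kidney_volume_source must be 'mask' or 'ellipsoid'")

    @property
    def effective_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return 0.5 * (self.background_intensity + self.particle_intensity)


def scaled_study_config(seed: int = 0, **overrides) -> StudyConfig:
    """A reduced-size study preserving the full-scale depth geometry.

    Kidneys are ~54-74 px in semi-axis at the native 0.1 mm spacing
    (about 1/5 of the real linear organ size) while the regime depth
    scales (40/60 px), depth cut-offs (50/100 px) and bead loads stay at
    their defaults, so the depth-stratified contrast between techniques is
    exercised at a size where whole replicate studies run in seconds.
    """
    base = StudyConfig(
        semi_axes_mm_ranges=((6.6, 7.4), (5.8, 6.6), (5.4, 6.0)),
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


def assign_sides(n_subjects: int) -> list[dict[str, str]]:
    """Per-subject technique-to-side map (subjects are 1-based).

    Odd subjects: left = pulsed, right = continuous. Even subjects: left =
    continuous, right = pulsed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = []
    for s in range(1, n_subjects + 1):
        if s % 2 == 1:
            out.append({"left": "pulsed", "right": "continuous"})
        else:
            out.append({"left": "continuous", "right": "pulsed"})
    return out


_SCALAR_METRICS = ("kidney_volume_ml", "embolic_volume_ml", "total_particle_count", "load_volume_ratio")


def _metric_value(q: KidneyQuantification, metric: str) -> float:
    if metric in _SCALAR_METRICS:
        return float(getattr(q, metric))
    kind, _, depth = metric.rpartition("_")
    dm = q.per_depth[int(depth)]
    lookup = {
        "pct_cortex": dm.percent_embolized_cortex,
        "efficiency": dm.efficiency_per_ml,
        "particles": dm.particle_count,
        "intersect": dm.intersect_voxels,
    }
    return float(lookup[kind])


@dataclass
class PairedStudyResult:
    """Per-kidney quantifications plus per-metric paired inference."""

    config: StudyConfig
    kidneys: list[KidneyQuantification]
    tests: dict[str, dict] = field(default_factory=dict)

    def metric_names(self) -> list[str]:
        names = list(_SCALAR_METRICS)
        for d in self.config.depths_px:
            names += [f"pct_cortex_{d}", f"efficiency_{d}", f"particles_{d}"]
        return names

    def metric_sample(self, metric: str) -> PairedSample:
        """Within-subject pairs for a metric: x = continuous, y = pulsed."""
        by_subject: dict[int, dict[str, float]] = {}
        for q in self.kidneys:
            by_subject.setdefault(q.subject, {})[q.regime] = _metric_value(q, metric)
        subjects = sorted(by_subject)
        x = [by_subject[s]["continuous"] for s in subjects]
        y = [by_subject[s]["pulsed"] for s in subjects]
        return PairedSample(subjects, x, y)

    def group_values(self, metric: str, regime: str) -> np.ndarray:
        return np.array(
            [_metric_value(q, metric) for q in self.kidneys if q.regime == regime]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q in self.kidneys:
            for d, dm in sorted(q.per_depth.items()):
                rows.append(
                    {
                        "subject": q.subject,
                        "side": q.side,
                        "regime": q.regime,
                        "kidney_id": q.kidney_id,
                        "kidney_volume_ml": q.kidney_volume_ml,
                        "embolic_volume_ml": q.embolic_volume_ml,
                        "load_volume_ratio": q.load_volume_ratio,
                        "total_particle_count": q.total_particle_count,
                        "depth_px": d,
                        "depth_mm": d * self.config.spacing_mm,
                        "intersect_voxels": dm.intersect_voxels,
                        "shell_voxels": dm.shell_voxels,
                        "particle_count": dm.particle_count,
                        "efficiency_per_ml": dm.efficiency_per_ml,
                        "percent_embolized_cortex": dm.percent_embolized_cortex,
                    }
                )
        columns = [
            "subject", "side", "regime", "kidney_id", "kidney_volume_ml",
            "embolic_volume_ml", "load_volume_ratio", "total_particle_count",
            "depth_px", "depth_mm", "intersect_voxels", "shell_voxels",
            "particle_count", "efficiency_per_ml", "percent_embolized_cortex",
        ]
        return pd.DataFrame(rows, columns=columns)

    def summary_dict(self) -> dict:
        """Group medians/ranges and paired tests per metric (JSON-ready)."""
        out: dict = {"n_subjects": self.config.n_subjects, "metrics": {}}
        for metric in self.metric_names():
            entry: dict = {}
            for regime in ("continuous", "pulsed"):
                vals = self.group_values(metric, regime)
                if vals.size:
                    entry[regime] = median_and_range(vals)
            entry["tests"] = {
                name: (
                    {
                        "statistic": t.statistic,
                        "p_two_sided": t.p_two_sided,
                        "method": t.method,
                        "n_effective": t.n_effective,
                    }
                    if isinstance(t, TestResult)
                    else {"error": t}
                )
                for name, t in self.tests.get(metric, {}).items()
            }
            out["metrics"][metric] = entry
        return out


def _run_tests(result: PairedStudyResult) -> None:
    for metric in result.metric_names():
        sample = result.metric_sample(metric)
        entry: dict = {}
        for name, fn in (
            ("paired_t", paired_t_test),
            ("wilcoxon", lambda s: wilcoxon_signed_rank(s, mode="exact" if s.n <= 20 else "normal")),
        ):
            try:
                entry[name] = fn(sample)
            except ValueError as exc:  # degenerate samples are reported, not fatal
                entry[name] = str(exc)
        result.tests[metric] = entry


def run_study(
    config: StudyConfig,
    out_dir: str | Path | None = None,
    keep_noise: bool = True,
) -> PairedStudyResult:
    """Simulate, segment, stratify, quantify and compare one paired study.

    Fully deterministic given ``config`` (including its seed). If
    ``out_dir`` is given, writes the per-kidney CSV and JSON summary there.
    ``keep_noise=False`` skips the CT-noise stage (used by exactness
    tests).
    """
    arms = {"continuous": config.continuous, "pulsed": config.pulsed}
    kidneys: list[KidneyQuantification] = []
    sides = assign_sides(config.n_subjects)
    seg = SegmentationParams(
        config.effective_threshold, config.min_component_voxels, config.connectivity
    )
    for subject in range(1, config.n_subjects + 1):
        for side_index, side in enumerate(("left", "right")):
            regime_name = sides[subject - 1][side]
            regime = arms[regime_name]
            child_seed = config.seed + subject * 10 + side_index
            rng = np.random.default_rng(child_seed)
            axes = tuple(float(rng.uniform(lo, hi)) for lo, hi in config.semi_axes_mm_ranges)
            spec = PhantomSpec(
                semi_axes_mm=axes,
                spacing_mm=config.spacing_mm,
                particle_radius_um_range=config.particle_radius_um_range,
                noise_sigma=config.noise_sigma,
                background_intensity=config.background_intensity,
                particle_intensity=config.particle_intensity,
            )
            try:
                ph = simulate_kidney(spec, regime, rng, noise=keep_noise)
                vessel = segment_particles(ph.volume, seg)
                volume_ml = None
                if config.kidney_volume_source == "ellipsoid":
                    volume_ml = ellipsoid_volume_ml(*(2 * a for a in axes))
                q = quantify_kidney(
                    vessel,
                    ph.kidney_mask,
                    config.depths_px,
                    kidney_id=f"s{subject}_{side}_{regime_name}",
                    subject=subject,
                    side=side,
                    regime=regime_name,
                    embolic_volume_ml=ph.embolic_volume_ml,
                    kidney_volume_ml=volume_ml,
                    connectivity=config.connectivity,
                    percent_denominator=config.percent_denominator,
                    distance_field=ph.distance_field,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline failed for subject {subject}, {side} kidney "
                    f"({regime_name})"
                ) from exc
            kidneys.append(q)
    result = PairedStudyResult(config, kidneys)
    if config.n_subjects >= 2:
        _run_tests(result)
    if out_dir is not None:
        write_results(result, out_dir)
    return result


_REGIME_KEYS = ("depth_scale_px", "particle_count_mean", "embolic_ml_low", "embolic_ml_high")


def load_study_config(path: str | Path) -> StudyConfig:
    """Read a flat ``key = value`` study config file.

    Recognized keys (all optional; omitted keys keep defaults):
    ``n_subjects``, ``seed``, ``depths_px`` (comma list), ``spacing_mm``,
    ``noise_sigma``, ``background_intensity``, ``particle_intensity``,
    ``threshold``, ``min_component_voxels``, ``connectivity``,
    ``percent_denominator``, ``kidney_volume_source``,
    ``semi_axis_{a|b|c}_mm`` ("low,high"), and per-regime keys
    ``{continuous|pulsed}_{depth_scale_px|particle_count_mean|embolic_ml_low|embolic_ml_high}``.
    Lines starting with ``#`` are comments.
    """
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        raw[key] = val

    kwargs: dict = {}
    simple_int = {"n_subjects", "seed", "min_component_voxels", "connectivity"}
    simple_float = {"spacing_mm", "noise_sigma", "background_intensity",
                    "particle_intensity", "threshold"}
    simple_str = {"percent_denominator", "kidney_volume_source"}
    axes = list(StudyConfig.semi_axes_mm_ranges)
    regimes = {"continuous": CONTINUOUS, "pulsed": PULSED}
    for key, val in raw.items():
        if key in simple_int:
            kwargs[key] = int(val)
        elif key in simple_float:
            kwargs[key] = float(val)
        elif key in simple_str:
            kwargs[key] = val
        elif key == "depths_px":
            kwargs[key] = tuple(int(v) for v in val.split(","))
        elif key.startswith("semi_axis_"):
            axis = "abc".index(key.removeprefix("semi_axis_").removesuffix("_mm"))
            lo, hi = (float(v) for v in val.split(","))
            axes[axis] = (lo, hi)
        else:
            arm, _, field_name = key.partition("_")
            if arm in regimes and field_name in _REGIME_KEYS:
                spec = regimes[arm]
                if field_name == "embolic_ml_low":
                    spec = replace(spec, embolic_ml_range=(float(val), spec.embolic_ml_range[1]))
                elif field_name == "embolic_ml_high":
                    spec = replace(spec, embolic_ml_range=(spec.embolic_ml_range[0], float(val)))
                else:
                    spec = replace(spec, **{field_name: float(val)})
                regimes[arm] = spec
            else:
                raise ValueError(f"unknown config key: {key!r}")
    kwargs["semi_axes_mm_ranges"] = tuple(axes)
    kwargs["continuous"] = regimes["continuous"]
    kwargs["pulsed"] = regimes["pulsed"]
    return StudyConfig(**kwargs)
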