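"""End-to-end pipeline driver: simulate -> tICA -> cluster -> MSM -> timescales.

Configuration is a flat ``key: value`` namespace (see ``DEFAULT_CONFIG``);
unknown keys are rejected so typos fail loudly.  Every run writes its
resolved configuration, per-stage outputs in plain-text formats and a
machine-readable ``summary`` manifest (slowest implied timescale, timescale
gap ratio, stationary entropy, state counts) into the run directory.  Given
the same seed and inputs the numeric outputs are byte-identical.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np

from . import io
from .cluster import KCenters, KMeansLloyd
from .coarse_grain import bace_merge
from .msm import count_transitions, estimate_nonreversible, estimate_reversible_mle, \
    implied_timescale_curves
from .synthetic import default_chain_spec, sample_lengths, simulate_chain
from .tica import TICA

__all__ = ["DEFAULT_CONFIG", "PipelineConfig", "run_pipeline", "StageError"]

DEFAULT_CONFIG: dict[str, object] = {
    "seed": 0,
    "chain.n_trajectories": 200,
    "chain.length_mean": 500.0,
    "chain.length_max": 5000,
    "chain.n_features": 10,
    "chain.emission_sd": 0.25,
    "tica.lag": 1,
    "tica.n_components": 2,
    "cluster.method": "kcenters",
    "cluster.k": 50,
    "msm.lag": 1,
    "msm.reversible": True,
    "timescales.lags": "1,2,5,10,20",
    "timescales.n": 3,
    "bace.n_macro": 0,  # 0 disables coarse-graining
}

_CASTS = {key: type(value) for key, value in DEFAULT_CONFIG.items()}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class PipelineConfig(dict):
    """Validated flat configuration; unknown keys are rejected."""

    def __init__(self, overrides: dict | None = None):
        super().__init__(DEFAULT_CONFIG)
        for key, value in (overrides or {}).items():
            if key not in DEFAULT_CONFIG:
                raise ValueError(f"unknown configuration key {key!r}")
            cast = _CASTS[key]
            if cast is bool and isinstance(value, str):
                value = value.lower() in ("1", "true", "yes")
            self[key] = cast(value)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls(io.read_manifest(path))

    def lags(self) -> list[int]:
        return [int(x) for x in str(self["timescales.lags"]).split(",")]


def _stage(name, func, log, *args, **kwargs):
    start = time.perf_counter()
    try:
        result = func(*args, **kwargs)
    except Exception as exc:
        raise StageError(name, exc) from exc
    log.append(f"stage={name} seconds={time.perf_counter() - start:.3f}")
    return result


def run_pipeline(config: PipelineConfig | dict, out_dir) -> dict:
    """Run the full chain on synthetic data and emit a summary manifest.

    Returns the summary as a dict; partial outputs are retained on failure.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_manifest(out / "config.txt", config)
    log: list[str] = []

    spec = default_chain_spec(
        seed=int(config["seed"]),
        n_trajectories=int(config["chain.n_trajectories"]),
        length_mean=float(config["chain.length_mean"]),
        length_max=int(config["chain.length_max"]),
        n_features=int(config["chain.n_features"]),
        emission_sd=float(config["chain.emission_sd"]),
    )
    lengths = _stage("lengths", sample_lengths, log, spec)
    true_labels, features = _stage("simulate", simulate_chain, log, spec, lengths)

    tica = _stage("tica", TICA(lag=int(config["tica.lag"])).fit, log, features)
    n_tics = int(config["tica.n_components"])
    projections = [tica.transform(f, n_components=n_tics) for f in features]
    pooled = np.vstack(projections)

    method = str(config["cluster.method"])
    k = int(config["cluster.k"])
    cls = {"kcenters": KCenters, "kmeans": KMeansLloyd}.get(method)
    if cls is None:
        raise StageError("cluster", ValueError(f"unknown method {method!r}"))
    clusterer = _stage("cluster", cls(k=k).fit, log, pooled)
    label_trajs = [clusterer.predict(p) for p in projections]
    labels_dir = out / "labels"
    labels_dir.mkdir(exist_ok=True)
    for i, labels in enumerate(label_trajs):
        io.write_labels(labels_dir / f"traj_{i:04d}.txt", labels)

    lag = int(config["msm.lag"])
    counts = _stage("counts", count_transitions, log, label_trajs, lag)
    est = estimate_reversible_mle if config["msm.reversible"] else estimate_nonreversible
    model = _stage("msm", est, log, counts)
    io.write_sparse_matrix(out / "counts.txt", counts.counts,
                           {"lag": lag, "n_states": counts.n_states})
    io.write_columnar(
        out / "spectrum.txt",
        np.column_stack([model.eigenvalues, model.implied_timescales]),
        header="mu_n tau_n",
    )

    curves = _stage(
        "timescales", implied_timescale_curves, log, label_trajs,
        config.lags(), int(config["timescales.n"]),
    )
    curves.to_csv(out / "timescales.tsv", sep="\t", index=False)

    n_macro = int(config["bace.n_macro"])
    if n_macro > 0:
        macro = _stage("bace", bace_merge, log, counts, n_macro)
        with open(out / "macrostate_map.txt", "w") as fh:
            for micro, m in enumerate(macro.mapping):
                fh.write(f"{micro}\t{m}\n")

    pi = model.stationary
    entropy = float(-(pi * np.log(pi, where=pi > 0, out=np.zeros_like(pi))).sum())
    tau = model.implied_timescales
    finite = tau[np.isfinite(tau)]
    summary = {
        "n_trajectories": len(label_trajs),
        "n_frames": int(sum(len(t) for t in label_trajs)),
        "n_microstates": counts.n_states,
        "tau_1": float(finite[0]) if finite.size else float("nan"),
        "gap_ratio": float(finite[0] / finite[1]) if finite.size > 1 else float("nan"),
        "stationary_entropy": entropy,
        "seed": int(config["seed"]),
    }
    io.write_manifest(out / "summary.txt", summary)
    (out / "run.log").write_text("\n".join(log) + "\n")
    return summary
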