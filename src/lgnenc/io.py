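"""Readers/writers for the package's on-disk formats and the pipeline driver.

Formats: spike trains as tab-separated event tables (neuron_id, time_ms)
with a commented header; stimuli as a dense TSV matrix (one row per ms, one
column per pixel) plus a JSON sidecar carrying grid shape, durations and
markers; model weights as .npz archives with a JSON config; run
configurations as YAML.  Every pipeline output embeds the config hash and
seed so a re-run reproduces it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from lgnenc import characterize, cnn, evaluate, glm
from lgnenc.preprocess import bin_rates
from lgnenc.simulate import SpikeData, default_population, simulate_population
from lgnenc.stimulus import (
    StimulusSequence,
    make_checkerboard,
    make_full_field,
    make_shapes,
    make_single_pixel,
    project_to_grid,
)

__all__ = [
    "write_spike_events",
    "read_spike_events",
    "write_stimulus",
    "read_stimulus",
    "save_model",
    "load_model",
    "config_hash",
    "run_pipeline",
]


def write_spike_events(path: str | Path, spikes: SpikeData) -> None:
    """Event-table writer: sorted (neuron_id, time_ms) rows, 1 ms resolution."""
    path = Path(path)
    times, neurons = np.nonzero(spikes.trains)
    order = np.lexsort((neurons, times))
    with path.open("w") as fh:
        fh.write(f"# n_neurons={spikes.n_neurons}\n")
        fh.write(f"# duration_ms={spikes.duration_ms}\n")
        fh.write("# resolution_ms=1\n")
        fh.write("neuron_id\ttime_ms\n")
        for i in order:
            fh.write(f"{spikes.neuron_ids[neurons[i]]}\t{times[i]}\n")


def read_spike_events(path: str | Path) -> SpikeData:
    path = Path(path)
    header: dict[str, int] = {}
    events: list[tuple[int, int]] = []
    bad: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = int(val)
                continue
            if line.startswith("neuron_id"):
                continue
            parts = line.split("\t")
            try:
                events.append((int(parts[0]), int(parts[1])))
            except (ValueError, IndexError):
                bad.append(lineno)
    if bad:
        raise ValueError(f"malformed event rows at lines: {bad}")
    if "n_neurons" not in header or "duration_ms" not in header:
        raise ValueError("missing n_neurons/duration_ms header")
    n, T = header["n_neurons"], header["duration_ms"]
    trains = np.zeros((T, n), dtype=np.uint8)
    prev = (-1, -1)
    for nid, t in events:
        if not (0 <= nid < n and 0 <= t < T):
            raise ValueError(f"event ({nid}, {t}) outside header bounds")
        if (t, nid) < prev:
            raise ValueError("event rows not sorted by (time_ms, neuron_id)")
        prev = (t, nid)
        trains[t, nid] = 1
    return SpikeData(trains=trains)


def write_stimulus(prefix: str | Path, stim: StimulusSequence) -> None:
    """Dense matrix TSV (`<prefix>.tsv`) + JSON sidecar (`<prefix>.json`)."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".tsv"), stim.frames, fmt="%d", delimiter="\t")
    sidecar = {
        "grid_shape": list(stim.grid_shape),
        "on_ms": stim.on_ms,
        "off_ms": stim.off_ms,
        "markers": [list(m) for m in stim.markers],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def read_stimulus(prefix: str | Path) -> StimulusSequence:
    prefix = Path(prefix)
    frames = np.loadtxt(prefix.with_suffix(".tsv"), dtype=np.uint8, delimiter="\t", ndmin=2)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return StimulusSequence(
        frames=frames,
        grid_shape=tuple(meta["grid_shape"]),
        on_ms=meta["on_ms"],
        off_ms=meta["off_ms"],
        markers=[tuple(m) for m in meta["markers"]],
    )


def save_model(prefix: str | Path, model: cnn.EncoderModel) -> None:
    prefix = Path(prefix)
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    np.savez(prefix.with_suffix(".npz"), **arrays)
    prefix.with_suffix(".json").write_text(json.dumps(model.cfg.__dict__))


def load_model(prefix: str | Path) -> cnn.EncoderModel:
    prefix = Path(prefix)
    cfg = cnn.EncoderConfig(**json.loads(prefix.with_suffix(".json").read_text()))
    model = cnn.build_model(cfg)
    with np.load(prefix.with_suffix(".npz")) as data:
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
    return model


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


STIM_BUILDERS = {
    "single_pixel": make_single_pixel,
    "checkerboard": make_checkerboard,
    "full_field": make_full_field,
}


def _build_stimulus(spec: dict, seed: int) -> StimulusSequence:
    kind = spec.get("kind", "checkerboard")
    kwargs = {k: v for k, v in spec.items() if k != "kind"}
    if "grid" in kwargs:
        kwargs["grid"] = tuple(kwargs["grid"])
    if kind == "shapes":
        if "canvas" in kwargs:
            kwargs["canvas"] = tuple(kwargs["canvas"])
        grid = kwargs.pop("grid", (4, 8))
        threshold = kwargs.pop("threshold", 0.25)
        return project_to_grid(make_shapes(seed=seed, **kwargs), grid=grid, threshold=threshold)
    if kind not in STIM_BUILDERS:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    if kind == "checkerboard":
        kwargs.setdefault("seed", seed)
    return STIM_BUILDERS[kind](**kwargs)


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Execute simulate -> bin -> characterize -> train/evaluate per config.

    Writes the evaluation report, neuron profiles, spike events and a summary
    (with seed, config hash and stage timings) under ``outdir``; idempotent
    for a fixed config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    h = config_hash(cfg)
    timings: dict[str, float] = {}
    summary: dict = {"seed": seed, "config_hash": h}

    t0 = time.perf_counter()
    stim = _build_stimulus(dict(cfg.get("stimulus", {})), seed)
    timings["stimulus"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pop_cfg = dict(cfg.get("population", {}))
    pop_cfg.setdefault("grid", stim.grid_shape)
    pop_cfg["grid"] = tuple(pop_cfg["grid"])
    specs = default_population(seed=seed, **pop_cfg)
    spikes = simulate_population(stim, specs, seed=seed)
    write_spike_events(outdir / "spikes.tsv", spikes)
    timings["simulate"] = time.perf_counter() - t0

    w_ms = int(cfg.get("w_ms", 50))
    rates = bin_rates(spikes, w_ms)

    t0 = time.perf_counter()
    profiles = characterize.profile_population(spikes, stim, w_ms=w_ms)
    prof_rows = [
        {
            "neuron_id": p.neuron_id,
            "r_db": p.r_db,
            "r_norm": p.r_norm,
            "tsr": p.tsr,
            "temporal_class": p.temporal_class,
            "spatial_class": p.spatial_class,
        }
        for p in profiles
    ]
    (outdir / "profiles.json").write_text(json.dumps(prof_rows, indent=1))
    timings["characterize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    model_cfg = dict(cfg.get("model", {}))
    model_kind = model_cfg.pop("kind", "cnn")
    if model_kind == "glm":
        L = int(model_cfg.pop("L", 500 // w_ms))
        params, X, row_bins = glm.fit_glm(stim, rates, L=L, **model_cfg)
        pred = glm.predict_rate(params, X)
        pred_full = np.full_like(rates.rates, np.nan, dtype=float)
        pred_full[row_bins] = pred
        tb = evaluate.trial_bins(stim.markers, w_ms, stim.trial_len_ms, rates.n_bins)
        per_neuron, _ = evaluate.prediction_correlation(rates.rates, pred_full, list(tb.values()))
        report_dict = {
            "per_neuron_corr": np.asarray(per_neuron).tolist(),
            "meta": {"model": "glm", "L": L},
        }
    else:
        enc_cfg = cnn.EncoderConfig(
            n_pixels=stim.n_pixels, n_neurons=spikes.n_neurons, w_ms=w_ms,
            seed=seed, **model_cfg,
        )
        report = evaluate.cross_validate(
            stim, rates, enc_cfg,
            scheme=cfg.get("scheme", "per_pattern"),
            k=int(cfg.get("folds", 5)),
            seed=seed,
        )
        report_dict = report.to_dict()
    timings["train_evaluate"] = time.perf_counter() - t0

    report_dict["seed"] = seed
    report_dict["config_hash"] = h
    (outdir / "eval_report.json").write_text(json.dumps(report_dict, sort_keys=True))
    summary["timings"] = {k: round(v, 3) for k, v in timings.items()}
    summary["outputs"] = ["spikes.tsv", "profiles.json", "eval_report.json"]
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return report_dict


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
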