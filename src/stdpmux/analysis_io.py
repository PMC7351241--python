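"""Spectral analysis, regime classification, file formats, and the CLI.

File formats (all plain text; see FORMATS.md at the repository root):
rasters and trajectories as CSV, configs/manifests/summaries as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time as _time
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import pandas as pd
from scipy import signal

from . import __version__
from .stdp_rules import STDPRule, rule_from_config, rule_to_config
from .synthetic_inputs import IntensityTrace, PopulationSpec, SpikeRaster

__all__ = [
    "SpectrogramResult",
    "RegimeLabel",
    "spectrogram",
    "mean_spectrum",
    "spectral_peak_db",
    "classify_regime",
    "write_raster_csv",
    "read_raster_csv",
    "write_intensity_csv",
    "read_intensity_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_manifest",
    "cli",
]


@dataclass
class SpectrogramResult:
    times: np.ndarray  # s, window centers
    freqs: np.ndarray  # Hz
    power_db: np.ndarray  # (n_freqs, n_times), dB relative to per-window max
    power: np.ndarray  # linear power, same shape
    window_s: float
    overlap: float


def spectrogram(
    post_spikes,
    duration: float,
    window_s: float = 2.0,
    overlap: float = 0.75,
    bin_ms: float = 1.0,
) -> SpectrogramResult:
    """Short-time spectrum of a spike train.

    Spikes are binned at ``bin_ms``, each Hann-tapered window is mean-removed
    (killing the DC rate peak), and power is expressed in dB relative to the
    per-window maximum.  Frequency resolution is ``1/window_s``.
    """
    post_spikes = np.asarray(post_spikes, dtype=float)
    if post_spikes.size == 0:
        raise ValueError("empty spike train")
    if duration < window_s:
        raise ValueError("recording shorter than one spectrogram window")
    bin_s = bin_ms / 1e3
    n_bins = int(round(duration / bin_s))
    counts = np.bincount(
        np.clip((post_spikes / bin_s).astype(int), 0, n_bins - 1), minlength=n_bins
    ).astype(float)
    nperseg = int(round(window_s / bin_s))
    freqs, times, sxx = signal.spectrogram(
        counts,
        fs=1.0 / bin_s,
        window="hann",
        nperseg=nperseg,
        noverlap=int(overlap * nperseg),
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    ref = np.maximum(sxx.max(axis=0, keepdims=True), 1e-300)
    power_db = 10.0 * np.log10(np.maximum(sxx, 1e-300) / ref)
    return SpectrogramResult(
        times=times, freqs=freqs, power_db=power_db, power=sxx,
        window_s=window_s, overlap=overlap,
    )


def mean_spectrum(result: SpectrogramResult, t_min: float = 0.0):
    """Time-averaged linear power spectrum (optionally from ``t_min`` on)."""
    mask = result.times >= t_min
    return result.freqs, result.power[:, mask].mean(axis=1)


def spectral_peak_db(
    freqs: np.ndarray,
    power: np.ndarray,
    target_hz: float,
    tol_hz: float = 1.0,
    floor_band=(2.0, 45.0),
) -> float:
    """Height of the peak near ``target_hz`` in dB over the median floor.

    The floor is the median power over ``floor_band`` excluding ±3 Hz around
    the target (robust to the peak itself).
    """
    near = (freqs >= target_hz - tol_hz) & (freqs <= target_hz + tol_hz)
    if not near.any():
        raise ValueError(f"no frequency bin within {tol_hz} Hz of {target_hz} Hz")
    floor_mask = (
        (freqs >= floor_band[0])
        & (freqs <= floor_band[1])
        & (np.abs(freqs - target_hz) > 3.0)
    )
    floor = float(np.median(power[floor_mask]))
    peak = float(power[near].max())
    return 10.0 * np.log10(max(peak, 1e-300) / max(floor, 1e-300))


@dataclass
class RegimeLabel:
    """Operational regime classification with its supporting evidence."""

    label: str  # NR | R | WTA | partial_R
    evidence: dict


def classify_regime(
    times,
    w_bar,
    w_tilde,
    spec_result: SpectrogramResult | None = None,
    frequencies=None,
    theta_w: float = 0.02,
    theta_s_db: float = 6.0,
    wta_ratio: float = 0.05,
    plateau_frac: float = 0.2,
) -> RegimeLabel:
    """Classify a weight trajectory (and optionally a downstream spectrum).

    Evidence is taken from the plateau window — the final ``plateau_frac`` of
    the run.  ``R`` needs every population's plateau ``w_tilde`` above
    ``theta_w`` (and, when a spectrogram is supplied, a peak of at least
    ``theta_s_db`` over the floor at every target frequency); ``WTA`` needs
    exactly one population's mean weight collapsed below ``wta_ratio`` of the
    largest; ``NR`` needs every ``w_tilde`` below ``theta_w``.  Anything else
    is ``partial_R``.  Thresholds operationalize qualitative regime
    descriptions; they are artifact choices, config-exposed.
    """
    times = np.asarray(times, dtype=float)
    w_bar = np.atleast_2d(np.asarray(w_bar, dtype=float))
    w_tilde = np.atleast_2d(np.asarray(w_tilde, dtype=float))
    mask = times >= times[-1] - plateau_frac * (times[-1] - times[0])
    if mask.sum() < 2:
        raise ValueError("trajectory too short for a plateau window")
    bar = w_bar[mask].mean(axis=0)
    tilde = w_tilde[mask].mean(axis=0)
    evidence = {"plateau_w_bar": bar.tolist(), "plateau_w_tilde": tilde.tolist()}
    peaks_ok = True
    if spec_result is not None and frequencies is not None:
        freqs, power = mean_spectrum(spec_result, t_min=times[-1] - plateau_frac * times[-1])
        peak_dbs = [spectral_peak_db(freqs, power, f) for f in frequencies]
        evidence["peak_db"] = peak_dbs
        peaks_ok = all(p >= theta_s_db for p in peak_dbs)
    if np.all(tilde > theta_w) and peaks_ok:
        return RegimeLabel("R", evidence)
    suppressed = bar < wta_ratio * bar.max()
    if suppressed.sum() == 1:
        return RegimeLabel("WTA", evidence)
    if np.all(tilde < theta_w):
        return RegimeLabel("NR", evidence)
    return RegimeLabel("partial_R", evidence)


# ---------------------------------------------------------------------------
# Text formats


def write_raster_csv(path, raster: SpikeRaster, spec: PopulationSpec | None = None) -> None:
    """Two-column CSV (neuron_id, spike_time_s at us precision) + JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("neuron_id,spike_time_s\n")
        for k, times in enumerate(raster.spikes):
            for t in times:
                fh.write(f"{k},{t:.6f}\n")
    sidecar = {
        "population_id": raster.population_id,
        "duration_s": raster.duration,
        "bin_width_s": raster.bin_width,
    }
    if spec is not None:
        sidecar["population_spec"] = dataclasses.asdict(spec)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_raster_csv(path) -> SpikeRaster:
    path = Path(path)
    df = pd.read_csv(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    n = int(df["neuron_id"].max()) + 1 if len(df) else 0
    if "population_spec" in meta:
        n = max(n, meta["population_spec"]["size"])
    spikes = [
        df.loc[df["neuron_id"] == k, "spike_time_s"].to_numpy() for k in range(n)
    ]
    return SpikeRaster(
        spikes=spikes,
        population_id=meta["population_id"],
        duration=meta["duration_s"],
        bin_width=meta["bin_width_s"],
    )


def write_intensity_csv(path, trace: IntensityTrace) -> None:
    cols = {"t_s": trace.times}
    for i in range(trace.values.shape[1]):
        cols[f"D{i + 1}_hz"] = trace.values[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_intensity_csv(path, refresh_period: float = 1.0) -> IntensityTrace:
    df = pd.read_csv(path)
    vcols = [c for c in df.columns if c != "t_s"]
    return IntensityTrace(
        times=df["t_s"].to_numpy(),
        values=df[vcols].to_numpy(),
        refresh_period=refresh_period,
    )


def write_trajectory_csv(path, times, w_bar, w_tilde, psi) -> None:
    """Long-format CSV: t_s, pop, w_bar, w_tilde, psi."""
    w_bar = np.atleast_2d(w_bar)
    rows = []
    for i, t in enumerate(np.asarray(times)):
        for p in range(w_bar.shape[1]):
            rows.append((t, p, w_bar[i, p], w_tilde[i, p], psi[i, p]))
    pd.DataFrame(rows, columns=["t_s", "pop", "w_bar", "w_tilde", "psi"]).to_csv(
        path, index=False
    )


def read_trajectory_csv(path):
    df = pd.read_csv(path)
    pops = sorted(df["pop"].unique())
    times = df.loc[df["pop"] == pops[0], "t_s"].to_numpy()
    stack = lambda col: np.column_stack(
        [df.loc[df["pop"] == p, col].to_numpy() for p in pops]
    )
    return times, stack("w_bar"), stack("w_tilde"), stack("psi")


def write_manifest(path, config: dict, seed, runtime_s: float, extra: dict | None = None) -> None:
    manifest = {
        "config": config,
        "seed": seed,
        "runtime_s": runtime_s,
        "versions": {
            "stdpmux": __version__,
            "numpy": np.__version__,
            "python": sys.version.split()[0],
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# CLI


def _load_config(path: str) -> dict:
    p = Path(path)
    try:
        text = p.read_text()
    except OSError as exc:
        raise click.UsageError(f"cannot read config {path}: {exc}")
    if p.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def _parse_rule(cfg: dict) -> STDPRule:
    if "rule" not in cfg:
        raise click.UsageError("config missing required block 'rule'")
    try:
        return rule_from_config(cfg["rule"])
    except (KeyError, ValueError, TypeError) as exc:
        raise click.UsageError(f"invalid 'rule' block: {exc}")


def _parse_populations(cfg: dict) -> list:
    if "populations" not in cfg:
        raise click.UsageError("config missing required block 'populations'")
    specs = []
    for i, block in enumerate(cfg["populations"]):
        try:
            specs.append(PopulationSpec(**block))
        except (TypeError, ValueError) as exc:
            raise click.UsageError(f"invalid populations[{i}]: {exc}")
    return specs


def _delay(cfg: dict) -> float:
    d = cfg.get("delay_ms", 10.0)
    if d < 0:
        raise click.UsageError("delay_ms must be non-negative")
    return d / 1e3


@click.group()
@click.version_option(__version__)
def cli():
    """Rhythmic-multiplexing STDP analysis toolkit."""


@cli.command()
@click.argument("config_path", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default=None, help="write JSON here instead of stdout")
def eigen(config_path, out):
    """Fixed point and stability eigenvalues for a config."""
    from . import stability

    cfg = _load_config(config_path)
    rule = _parse_rule(cfg)
    specs = _parse_populations(cfg)
    es = stability.eigenvalues(rule, specs, _delay(cfg))
    payload = {
        "fixed_point": dataclasses.asdict(es.fixed_point),
        "lambda_u": es.lambda_u,
        "lambda_wta": es.lambda_wta,
        "lambda_rhythmic": {str(k): v for k, v in es.lambda_rhythmic.items()},
        "lambda_rhythmic_dyn": {str(k): v for k, v in es.lambda_rhythmic_dyn.items()},
        "q_tilde": {str(k): v for k, v in es.q_tilde.items()},
    }
    text = json.dumps(payload, indent=1)
    if out:
        Path(out).write_text(text)
    else:
        click.echo(text)


@cli.command("phase-diagram")
@click.argument("config_path", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), required=True)
def phase_diagram_cmd(config_path, out):
    """Regime-label grid over two parameter axes (CSV)."""
    from . import stability

    cfg = _load_config(config_path)
    rule = _parse_rule(cfg)
    specs = _parse_populations(cfg)
    axes = []
    for key in ("axis1", "axis2"):
        if key not in cfg:
            raise click.UsageError(f"config missing required block '{key}'")
        blk = cfg[key]
        try:
            axes.append((blk["name"], np.linspace(blk["start"], blk["stop"], blk["num"])))
        except KeyError as exc:
            raise click.UsageError(f"'{key}' missing field {exc}")
    df = stability.phase_diagram(
        axes[0], axes[1], rule, specs, _delay(cfg),
        convention=cfg.get("convention", "printed"),
    )
    df.to_csv(out, index=False)
    click.echo(f"wrote {out}")


@cli.command("meanfield")
@click.argument("config_path", type=click.Path(exists=True))
@click.option("--outdir", type=click.Path(), required=True)
def meanfield_cmd(config_path, outdir):
    """Integrate the slow-learning mean-field dynamics."""
    from . import meanfield as mf

    t_start = _time.time()
    cfg = _load_config(config_path)
    rule = _parse_rule(cfg)
    specs = _parse_populations(cfg)
    init = cfg.get("initial", {"kind": "random", "low": 0.0, "high": 1.0, "seed": 0})
    state = mf.initial_state(
        specs, kind=init.get("kind", "random"), low=init.get("low", 0.0),
        high=init.get("high", 1.0), rng=init.get("seed", 0),
    )
    traj = mf.integrate_meanfield(
        state, rule, specs, _delay(cfg),
        horizon=cfg.get("horizon_s", 1000.0),
        step=cfg.get("step_s", 1.0),
        output_stride=cfg.get("output_stride_s", 1.0),
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trajectory_csv(outdir / "trajectory.csv", traj.times, traj.w_bar, traj.w_tilde, traj.psi)
    regime = classify_regime(
        traj.times, traj.w_bar, traj.w_tilde,
        theta_w=cfg.get("theta_w", 0.02),
    )
    write_manifest(
        outdir / "manifest.json", cfg, init.get("seed", 0), _time.time() - t_start,
        extra={"regime": regime.label, "evidence": regime.evidence},
    )
    click.echo(f"regime: {regime.label}; wrote {outdir}/trajectory.csv")


@cli.command()
@click.argument("config_path", type=click.Path(exists=True))
@click.option("--outdir", type=click.Path(), required=True)
def simulate(config_path, outdir):
    """Run a spiking simulation (linear Poisson or conductance-based)."""
    from . import spiking_sim as sim

    t_start = _time.time()
    cfg = _load_config(config_path)
    rule = _parse_rule(cfg)
    specs = _parse_populations(cfg)
    kind = cfg.get("neuron", "linear")
    seed = cfg.get("seed", 0)
    duration = cfg.get("duration_s", 100.0)
    if kind == "linear":
        neuron = sim.LinearPoissonNeuron(delay=_delay(cfg))
        result = sim.run_linear_poisson(specs, rule, neuron, duration, seed=seed)
    elif kind == "conductance":
        neuron = sim.ConductanceNeuron(g_a=cfg.get("gA_mS_cm2", 20.0))
        result = sim.run_conductance(specs, rule, neuron, duration, seed=seed)
    else:
        raise click.UsageError(f"neuron must be 'linear' or 'conductance', got {kind!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trajectory_csv(outdir / "weights.csv", result.times, result.w_bar, result.w_tilde, result.psi)
    pd.DataFrame({"spike_time_s": result.post_spikes}).to_csv(outdir / "post_spikes.csv", index=False)
    write_manifest(outdir / "manifest.json", cfg, seed, _time.time() - t_start)
    click.echo(f"wrote {outdir}")


@cli.command()
@click.argument("rundir", type=click.Path(exists=True))
@click.option("--frequencies", required=True, help="comma-separated target Hz")
@click.option("--out", type=click.Path(), default=None)
def analyze(rundir, frequencies, out):
    """Spectrogram + regime classification of a simulate output directory."""
    rundir = Path(rundir)
    try:
        freqs = [float(f) for f in frequencies.split(",")]
    except ValueError:
        raise click.UsageError("--frequencies must be comma-separated numbers")
    post = pd.read_csv(rundir / "post_spikes.csv")["spike_time_s"].to_numpy()
    times, w_bar, w_tilde, psi = read_trajectory_csv(rundir / "weights.csv")
    duration = float(times[-1])
    spec_res = spectrogram(post, duration)
    regime = classify_regime(times, w_bar, w_tilde, spec_res, freqs)
    payload = {"regime": regime.label, "evidence": regime.evidence}
    text = json.dumps(payload, indent=1)
    if out:
        Path(out).write_text(text)
    else:
        click.echo(text)
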