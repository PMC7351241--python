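# stdpmux

Tools for studying whether spike-timing-dependent plasticity (STDP) can
spontaneously develop frequency-division multiplexing: two (or more) rhythmic
pre-synaptic populations, organized on rings of preferred phases, drive one
downstream neuron through plastic synapses.  The package provides

- **`stdpmux.stdp_rules`** — temporally asymmetric (exponential) and symmetric
  (difference-of-Gaussians) STDP kernels, soft-bound weight dependence
  `f_+(w) = (1-w)^mu`, `f_-(w) = alpha*w^mu`, kernel Fourier transforms, and
  all-pairs spike-pair updates;
- **`stdpmux.synthetic_inputs`** — piecewise-constant stimulus-intensity
  processes (e.g. `7 + U(0,6)` Hz resampled each second) and ring-organized
  inhomogeneous Poisson spike rasters with rate
  `D(t) * (1 + gamma*cos(nu*t - phi_k))`;
- **`stdpmux.meanfield`** — deterministic slow-learning weight dynamics on the
  ring, order parameters (mean weight `w_bar`, first Fourier magnitude/phase
  `w_tilde`, `psi`), and limit-cycle phase-velocity fits;
- **`stdpmux.stability`** — closed-form homogeneous fixed point (`alpha_c`,
  `X_±`, `w*`), the uniform / winner-take-all / rhythmic eigenvalues, the
  kernel-spectrum gate `Q~`, and NR / R / WTA / partial-R phase diagrams;
- **`stdpmux.spiking_sim`** — finite-learning-rate simulations with a linear
  Poisson downstream neuron (characteristic delay `d`) or a conductance-based
  Hodgkin–Huxley neuron with a transient potassium A-current (threshold-linear
  f-I curve) and alpha-function synapses; online all-pairs STDP applied every
  second of simulated time;
- **`stdpmux.analysis_io`** — spike-train spectrograms, regime classification,
  plain-text file formats (see `FORMATS.md`), and the `stdpmux` CLI.

A note on the rhythmic eigenvalue: the package reports it in two conventions
(`lambda_rhythmic` and `lambda_rhythmic_dyn`) that differ by a constant factor
in the oscillation-gated term; the `_dyn` value is the exact linear growth rate
of the implemented mean-field dynamics (verified by perturbation tests), while
the plain value matches the commonly quoted closed form.  See the
`stdpmux.stability` module docstring.

## CLI

All subcommands take a JSON (or YAML) config; shared blocks are `rule`,
`populations`, and `delay_ms`:

```json
{
  "rule": {"family": "asymmetric", "tau_plus_ms": 20, "tau_minus_ms": 50,
           "alpha": 1.05, "mu": 0.01, "learning_rate": 0.001},
  "populations": [
    {"size": 120, "freq_hz": 5, "gamma": 1.0, "intensity_mean": 10, "sigma": 0.6},
    {"size": 120, "freq_hz": 9, "gamma": 1.0, "intensity_mean": 10, "sigma": 0.6}
  ],
  "delay_ms": 10
}
```

```bash
stdpmux eigen config.json                       # fixed point + eigenvalues (JSON)
stdpmux phase-diagram config.json --out grid.csv  # needs axis1/axis2 blocks
stdpmux meanfield config.json --outdir run/     # trajectory CSV + manifest
stdpmux simulate config.json --outdir sim/      # spiking run (linear|conductance)
stdpmux analyze sim/ --frequencies 5,9          # spectrogram + regime label
```

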