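"""Config-driven end-to-end runs and ISI tail diagnostics.

A single YAML config drives the whole pipeline — inputs (spike files or
simulation specs), scale grid, moment orders, detrending order, surrogates
— and all randomness flows from one root seed through named substreams
(``simulate``, ``shuffle``, ``bootstrap``, ``split``), so each component is
independently reproducible.  Outputs are CSV tables, figures, and a JSON
manifest of every parameter and interpretation flag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigError, InsufficientDataError, ParameterError
from .castaing import BRACKET_Q, DEFAULT_Q, lambda_curve
from .fluctuation import fluctuation_field, make_scales
from .io import ISISeries, read_spike_times, to_isi
from .magnitude import magnitude_corr, scale_collapse
from .simulate import (
    CascadeParams,
    RenewalParams,
    gen_cascade_isi,
    gen_poisson,
    gen_renewal,
    shuffle_isi,
)

_SUBSTREAMS = ("simulate", "shuffle", "bootstrap", "split")


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one root seed."""
    if name not in _SUBSTREAMS:
        raise ConfigError(f"unknown substream {name!r}")
    ss = np.random.SeedSequence(int(root_seed))
    children = ss.spawn(len(_SUBSTREAMS))
    return np.random.default_rng(children[_SUBSTREAMS.index(name)])


def _simulate(spec: dict, rng: np.random.Generator) -> ISISeries:
    model = spec.get("model")
    n = int(spec.get("n_events", 2 ** 14))
    if model == "poisson":
        return to_isi(gen_poisson(float(spec.get("rate", 1.0)), n, rng))
    if model == "renewal":
        keys = ("family", "rate", "shape", "scale", "alpha", "cutoff")
        params = RenewalParams(**{k: spec[k] for k in keys if k in spec})
        return gen_renewal(params, n, rng)
    if model == "cascade":
        params = CascadeParams(
            depth=int(spec.get("depth", int(np.ceil(np.log2(n))))),
            level_var=float(spec.get("level_var", 0.05)),
            mean_isi=float(spec.get("mean_isi", 1.0)),
            noise_eps=float(spec.get("noise_eps", 0.1)),
        )
        return gen_cascade_isi(params, n, rng)
    raise ConfigError(f"unknown simulation model {model!r}")


def _load_inputs(cfg: dict, rng_sim) -> dict[str, ISISeries]:
    series = {}
    for item in cfg.get("inputs", []):
        name = item.get("name")
        if not name:
            raise ConfigError("each input needs a 'name' key")
        if "path" in item:
            path = Path(item["path"])
            if not path.exists():
                raise ConfigError(f"input path not found for key {name!r}: {path}")
            trains = read_spike_times(path, format=item.get("format", "plain"))
            for tr in trains:
                label = name if len(trains) == 1 else f"{name}/{tr.unit_id}"
                series[label] = to_isi(tr)
        elif "simulate" in item:
            series[name] = _simulate(item["simulate"], rng_sim)
        else:
            raise ConfigError(f"input {name!r} needs 'path' or 'simulate'")
    if not series:
        raise ConfigError("config lists no inputs")
    return series


def run(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute a full analysis described by a config mapping or YAML path.

    Writes ``lambda.csv``, ``magcorr.csv``, ``manifest.json`` and figures
    under ``outdir`` (default: config key ``outdir`` or ``./results``) and
    returns the tables in memory.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    sc = cfg.get("scales", {}) or {}
    scales = make_scales(
        int(sc.get("min", 4)), int(sc.get("max", 582)), int(sc.get("count", 10))
    )
    q_list = [float(q) for q in cfg.get("q", [DEFAULT_Q, BRACKET_Q])]
    order = int(cfg.get("detrend", {}).get("order", 3))
    do_surrogates = bool(cfg.get("surrogates", True))
    n_boot = int(cfg.get("n_boot", 200))
    mag_scales = [int(s) for s in cfg.get("magnitude_scales", [25, 50, 100])]

    rng_sim = _simulate_rng = substream(seed, "simulate")
    rng_shuf = substream(seed, "shuffle")
    rng_boot = substream(seed, "bootstrap")

    series = _load_inputs(cfg, rng_sim)

    lam_rows, mag_rows, failures = [], [], []
    collapse_stats = {}
    for name, isi in series.items():
        variants = {"original": isi}
        if do_surrogates:
            variants["shuffled"] = shuffle_isi(isi, rng_shuf)
        for variant, s_isi in variants.items():
            for q in q_list:
                try:
                    lc = lambda_curve(
                        s_isi, scales=scales, q=q, order=order,
                        n_boot=n_boot, seed=rng_boot,
                        source={"name": name, "variant": variant},
                    )
                except (InsufficientDataError, ParameterError) as err:
                    failures.append({"name": name, "variant": variant,
                                     "q": q, "reason": str(err)})
                    continue
                for i in range(len(lc)):
                    lam_rows.append({
                        "name": name, "variant": variant, "q": q,
                        "scale": int(lc.scales[i]),
                        "lambda2": float(lc.lambda2[i]),
                        "se": float(lc.se[i]),
                        "n_values": int(lc.n_values[i]),
                    })
        try:
            flucts = fluctuation_field(isi, scales=mag_scales, order=order)
            curves = [magnitude_corr(fs) for fs in flucts]
            for c in curves:
                for i in range(len(c.lags)):
                    mag_rows.append({
                        "name": name, "scale": c.scale_s,
                        "lag": int(c.lags[i]), "corr": float(c.corr[i]),
                        "n_pairs": int(c.n_pairs[i]),
                    })
            if len(curves) >= 2:
                collapse_stats[name] = scale_collapse(curves)["statistic"]
        except (InsufficientDataError, ParameterError) as err:
            failures.append({"name": name, "variant": "magnitude",
                             "q": None, "reason": str(err)})

    lam_df = pd.DataFrame(lam_rows)
    mag_df = pd.DataFrame(mag_rows)
    manifest = {
        "seed": seed,
        "scales": scales,
        "q": q_list,
        "detrend_order": order,
        "n_boot": n_boot,
        "magnitude_scales": mag_scales,
        "surrogates": do_surrogates,
        "flags": {
            "fluctuation_variant": "lag-s increment of windowed residual",
            "magnitude_variant": "pearson-log-energy",
            "epoch_rule": "boundary-ISIs-excluded",
        },
        "collapse_statistic": collapse_stats,
        "failures": failures,
        "inputs": sorted(series),
    }

    out = Path(outdir if outdir is not None else cfg.get("outdir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    lam_df.to_csv(out / "lambda.csv", index=False)
    mag_df.to_csv(out / "magcorr.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if cfg.get("figures", True) and not lam_df.empty:
        _plot(lam_df, mag_df, out)
    return {"lambda": lam_df, "magcorr": mag_df, "manifest": manifest}


def _plot(lam_df: pd.DataFrame, mag_df: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for logy, fname in ((False, "lambda_loglinear.png"),
                        (True, "lambda_loglog.png")):
        fig, ax = plt.subplots(figsize=(5, 4))
        for (name, variant, q), grp in lam_df.groupby(["name", "variant", "q"]):
            if q != lam_df["q"].min():
                continue
            ls = "-" if variant == "original" else "--"
            ax.errorbar(grp["scale"], grp["lambda2"], yerr=grp["se"],
                        ls=ls, marker="o", ms=3, label=f"{name} ({variant})")
        ax.set_xscale("log")
        if logy:
            ax.set_yscale("log")
        ax.set_xlabel("scale s (ISI count)")
        ax.set_ylabel(r"$\lambda^2$")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / fname, dpi=120)
        plt.close(fig)
    if not mag_df.empty:
        fig, ax = plt.subplots(figsize=(5, 4))
        for (name, s), grp in mag_df.groupby(["name", "scale"]):
            pos = grp[grp["lag"] > 0]
            ax.plot(pos["lag"], pos["corr"], marker="o", ms=3,
                    label=f"{name} s={s}")
        ax.set_xscale("log")
        ax.set_xlabel("lag l (ISI count)")
        ax.set_ylabel("C(l)/C(0)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "magnitude_correlation.png", dpi=120)
        plt.close(fig)


def isi_tail_diagnostics(
    series: ISISeries,
    n_bins: int = 40,
    tail_quantile: float = 0.5,
) -> dict:
    """Compare exponential vs power-law descriptions of the ISI tail.

    The ISI histogram is log-binned; the tail (above the given quantile) is
    fitted by least squares in log-linear coordinates (log density vs x —
    linear for an exponential tail) and in log-log coordinates (log density
    vs log x — linear for a power-law tail).  Both slopes and residual sums
    of squares are reported so the better-supported family can be judged;
    this is a diagnostic, not a rigorous power-law inference.
    """
    if len(series) < 1000:
        raise ParameterError("tail diagnostics need >= 1000 ISIs")
    x = series.values
    edges = np.geomspace(x.min(), x.max() * (1 + 1e-12), n_bins + 1)
    counts, edges = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / (widths * x.size)
    thresh = np.quantile(x, tail_quantile)
    mask = (centers >= thresh) & (density > 0)
    if mask.sum() < 3:
        raise InsufficientDataError("too few occupied bins in the tail range")
    cx, cd = centers[mask], np.log(density[mask])

    def _fit(abscissa):
        A = np.vstack([abscissa, np.ones_like(abscissa)]).T
        coef, rss, *_ = np.linalg.lstsq(A, cd, rcond=None)
        resid = cd - A @ coef
        return float(coef[0]), float(np.sum(resid ** 2))

    slope_lin, rss_lin = _fit(cx)           # exponential: log p ~ -x/tau
    slope_log, rss_log = _fit(np.log(cx))   # power law: log p ~ -alpha log x
    return {
        "threshold": float(thresh),
        "n_tail_bins": int(mask.sum()),
        "loglinear": {"slope": slope_lin, "rss": rss_lin},
        "loglog": {"slope": slope_log, "rss": rss_log},
        "preferred": "exponential" if rss_lin < rss_log else "powerlaw",
    }
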