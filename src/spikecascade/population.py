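"""Group-level comparisons of lambda^2 curves.

Per-scale paired awake/asleep tests across units, single-tetrode
superposed-train analysis with shuffled surrogates, and the over-division
consistency check: splitting one train into two children should leave the
parent's lambda^2 interleaved between the children's values, because the
parent's fluctuation PDF is approximately the mean of the children's.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import InsufficientDataError, ParameterError
from .castaing import LambdaCurve, estimate_lambda2, lambda_curve
from .fluctuation import cumulate, detrended_increments
from .io import ISISeries, SpikeTrain, superpose, to_isi
from .simulate import shuffle_isi, split_train

logger = logging.getLogger(__name__)


def group_lambda(curves: list[LambdaCurve]) -> pd.DataFrame:
    """Per-scale mean, SEM = SD/sqrt(n) and n over a set of units.

    Units missing a scale are excluded pairwise at that scale.
    """
    if not curves:
        raise ParameterError("empty curve list")
    qs = {c.q for c in curves}
    if len(qs) > 1:
        raise ParameterError(f"curves mix moment orders {sorted(qs)}")
    all_scales = sorted({int(s) for c in curves for s in c.scales})
    rows = []
    for s in all_scales:
        vals = []
        for c in curves:
            hit = np.flatnonzero(c.scales == s)
            if hit.size:
                vals.append(float(c.lambda2[hit[0]]))
        vals = np.asarray(vals)
        n = vals.size
        rows.append({
            "scale": s,
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            "n": n,
        })
    return pd.DataFrame(rows)


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def paired_state_test(
    awake: list[LambdaCurve],
    asleep: list[LambdaCurve],
    pairing: list | None = None,
) -> pd.DataFrame:
    """Per-scale two-sided paired t-test of awake vs asleep lambda^2.

    ``pairing`` optionally gives unit ids aligning the two lists; by default
    they are paired positionally.  The mean difference follows the
    convention awake - asleep.  Zero-variance differences are reported with
    p = NaN and flagged ``degenerate`` rather than raising.  A
    Holm-adjusted column accompanies the raw per-scale p-values.
    """
    if pairing is not None:
        key_a = {c.source.get("unit_id"): c for c in awake}
        key_s = {c.source.get("unit_id"): c for c in asleep}
        try:
            awake = [key_a[u] for u in pairing]
            asleep = [key_s[u] for u in pairing]
        except KeyError as err:
            raise ParameterError(f"unit {err} missing a state curve")
    if len(awake) != len(asleep):
        raise ParameterError("paired test needs equal-length curve lists")
    if len(awake) < 3:
        raise ParameterError("paired test needs >= 3 unit pairs")
    scales = sorted(
        {int(s) for c in awake for s in c.scales}
        & {int(s) for c in asleep for s in c.scales}
    )
    rows = []
    for s in scales:
        diffs = []
        for ca, cs in zip(awake, asleep):
            ha = np.flatnonzero(ca.scales == s)
            hs = np.flatnonzero(cs.scales == s)
            if ha.size and hs.size:
                diffs.append(float(ca.lambda2[ha[0]] - cs.lambda2[hs[0]]))
        d = np.asarray(diffs)
        n = d.size
        row = {"scale": s, "n_pairs": n, "mean_diff": float(d.mean())}
        if n >= 2 and d.std(ddof=1) > 0:
            res = stats.ttest_1samp(d, 0.0)
            row.update(t=float(res.statistic), df=n - 1,
                       p=float(res.pvalue), degenerate=False)
        else:
            row.update(t=np.nan, df=n - 1, p=np.nan, degenerate=True)
        rows.append(row)
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["p_holm"] = np.nan
    if ok.any():
        df.loc[ok, "p_holm"] = _holm(df.loc[ok, "p"].to_numpy())
    return df


def tetrode_pipeline(
    tetrodes: dict[str, list[SpikeTrain]] | list[list[SpikeTrain]],
    scales: list[int] | None = None,
    q: float = 0.25,
    order: int = 3,
    n_boot: int = 200,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Superposed single-tetrode lambda^2 curves with shuffled surrogates.

    For each tetrode the member units are superposed into one train, its
    ISI series analyzed, and a shuffled-ISI surrogate analyzed alongside.
    Returns per-tetrode original and shuffled curves plus group summaries.
    """
    if isinstance(tetrodes, list):
        tetrodes = {str(i): trs for i, trs in enumerate(tetrodes)}
    if not tetrodes:
        raise ParameterError("no tetrodes given")
    rng = np.random.default_rng(seed)
    originals, shuffled = {}, {}
    for tet_id, trains in tetrodes.items():
        merged = superpose(trains)
        isi = to_isi(merged)
        src = {"tetrode_id": tet_id, "kind": "tetrode"}
        originals[tet_id] = lambda_curve(
            isi, scales=scales, q=q, order=order, n_boot=n_boot, seed=rng,
            source=src,
        )
        shuffled[tet_id] = lambda_curve(
            shuffle_isi(isi, rng), scales=scales, q=q, order=order,
            n_boot=n_boot, seed=rng, source={**src, "surrogate": "shuffled"},
        )
    return {
        "curves": originals,
        "shuffled": shuffled,
        "group": group_lambda(list(originals.values())),
        "group_shuffled": group_lambda(list(shuffled.values())),
    }


def _block_isi(child: SpikeTrain) -> ISISeries:
    """Within-block ISIs of a split child; boundary-spanning gaps excluded."""
    cuts = np.asarray(child.meta.get("cut_points", ()))
    isis = np.diff(child.times)
    if cuts.size:
        left = np.searchsorted(cuts, child.times[:-1], side="right")
        right = np.searchsorted(cuts, child.times[1:], side="right")
        isis = isis[left == right]
    return ISISeries(values=isis, source={
        "unit_id": child.unit_id, "epoch_rule": "boundary-ISIs-excluded",
    })


def _blockwise_sem(values: np.ndarray, segment_index: np.ndarray) -> float:
    """SEM of the mean computed over per-segment (window) means."""
    seg = np.asarray(segment_index)
    bounds = np.searchsorted(seg, np.unique(seg))
    counts = np.diff(np.append(bounds, values.size))
    means = np.add.reduceat(values, bounds) / counts
    k = means.size
    if k < 2:
        return float(np.std(values, ddof=1) / np.sqrt(values.size))
    return float(np.std(means, ddof=1) / np.sqrt(k))


def _scale_moments(series: ISISeries, scales, q, order):
    """Per-scale (sigma_s, raw fluctuations) for the over-division identity."""
    prof = cumulate(series)
    out = {}
    for s in scales:
        try:
            out[s] = detrended_increments(prof, s, order=order)
        except InsufficientDataError:
            logger.warning("scale_skipped reason=too_short scale=%d", s)
    return out


def overdivision_check(
    parent: ISISeries | SpikeTrain,
    d: float,
    scales: list[int] | None = None,
    q: float = 0.25,
    seed: int | np.random.Generator | None = None,
    order: int = 3,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Over-division consistency report for an artificial train split.

    The parent train is split into two children with uniform(0, d) cut
    gaps.  A child's ISIs are taken within its own blocks only: the
    intervals spanning a removed block are excluded, consistent with the
    epoch-boundary rule, since those gaps are artifacts of the division
    rather than inter-spike intervals the child neuron produced.  Per
    usable scale the report carries lambda^2 of parent and children with
    bootstrap SEs and checks the interleaving property

        min(child1, child2) - 3 SE <= parent <= max(child1, child2) + 3 SE,

    together with the q-moment mixture identity: with all three fluctuation
    samples standardized by the parent's sigma_s,
    mean|x|^q (parent) ~ [mean|x|^q (c1) + mean|x|^q (c2)] / 2 within a
    3-sigma bootstrap band.
    """
    rng = np.random.default_rng(seed)
    if isinstance(parent, ISISeries):
        parent_train = SpikeTrain(
            times=np.cumsum(parent.values), unit_id="parent"
        )
        parent_isi = parent
    else:
        parent_train = parent
        parent_isi = to_isi(parent)
    c1, c2 = split_train(parent_train, d, rng)
    if len(c1) < 3 or len(c2) < 3:
        raise InsufficientDataError("children too short after split")
    isi1, isi2 = (_block_isi(c) for c in (c1, c2))
    if scales is None:
        from .fluctuation import make_scales
        scales = make_scales()
    fl_p = _scale_moments(parent_isi, scales, q, order)
    fl_1 = _scale_moments(isi1, scales, q, order)
    fl_2 = _scale_moments(isi2, scales, q, order)
    rows = []
    for s in sorted(set(fl_p) & set(fl_1) & set(fl_2)):
        fp, f1, f2 = fl_p[s], fl_1[s], fl_2[s]
        if min(len(fp), len(f1), len(f2)) < 50:
            logger.warning("scale_skipped reason=too_few_values scale=%d", s)
            continue
        lam_p, se_p = estimate_lambda2(fp.standardized, q=q, n_boot=n_boot,
                                       seed=rng, segment_index=fp.segment_index)
        lam_1, se_1 = estimate_lambda2(f1.standardized, q=q, n_boot=n_boot,
                                       seed=rng, segment_index=f1.segment_index)
        lam_2, se_2 = estimate_lambda2(f2.standardized, q=q, n_boot=n_boot,
                                       seed=rng, segment_index=f2.segment_index)
        lo = min(lam_1, lam_2) - 3.0 * max(se_1, se_2, se_p)
        hi = max(lam_1, lam_2) + 3.0 * max(se_1, se_2, se_p)
        interleaved = lo <= lam_p <= hi
        # moment identity in the parent's units: children standardized by
        # the parent's sigma_s so the mixture relation holds in expectation
        mq_p = np.abs(fp.raw / fp.sigma_s) ** q
        mq_1 = np.abs(f1.raw / fp.sigma_s) ** q
        mq_2 = np.abs(f2.raw / fp.sigma_s) ** q
        mix = 0.5 * (mq_1.mean() + mq_2.mean())
        # SEs over per-window means: values within a detrending window are
        # dependent, so an iid SE would be optimistic
        mse_1 = _blockwise_sem(mq_1, f1.segment_index)
        mse_2 = _blockwise_sem(mq_2, f2.segment_index)
        se_mix = 0.5 * np.hypot(mse_1, mse_2)
        se_par = _blockwise_sem(mq_p, fp.segment_index)
        moment_ok = abs(mq_p.mean() - mix) <= 3.0 * np.hypot(se_mix, se_par) \
            + 0.02 * mq_p.mean()
        rows.append({
            "scale": s,
            "lambda2_parent": lam_p, "se_parent": se_p,
            "lambda2_child1": lam_1, "se_child1": se_1,
            "lambda2_child2": lam_2, "se_child2": se_2,
            "interleave_lo": lo, "interleave_hi": hi,
            "interleaved": bool(interleaved),
            "moment_parent": float(mq_p.mean()),
            "moment_children_mean": float(mix),
            "moment_ok": bool(moment_ok),
        })
    if not rows:
        raise InsufficientDataError("no usable scale for over-division check")
    return pd.DataFrame(rows)
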