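"""Independent brute-force recomputations used as test oracles.

Everything here iterates over raw records with plain Python loops and its
own window arithmetic — deliberately sharing no code with the package's
aggregation paths.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

NAN = float("nan")


def sub_months(t: pd.Timestamp, w: int) -> pd.Timestamp:
    y, m = t.year, t.month - w
    while m <= 0:
        y, m = y - 1, m + 12
    return pd.Timestamp(y, m, 1)


def _window_cases(corpus, aff, t, w):
    lo = sub_months(t, w)
    return [
        r
        for r in corpus.cases.itertuples(index=False)
        if r.affiliate_id == aff and lo <= r.received_date < t
    ]


def _window_subs(corpus, aff, t, w):
    lo = sub_months(t, w)
    case_info = {
        r.case_id: (r.affiliate_id, r.received_date)
        for r in corpus.cases.itertuples(index=False)
    }
    out = []
    for s in corpus.submissions.itertuples(index=False):
        info = case_info.get(s.case_id)
        if info is None:
            continue
        a, received = info
        if a == aff and lo <= received < t:
            out.append(s)
    return out


def _ratio(num: int, den: int) -> float:
    return NAN if den == 0 else num / den


def _nearest_rank(values, q):
    if not values:
        return NAN
    s = sorted(values)
    return float(s[max(math.ceil(q * len(s)), 1) - 1])


def oracle_feature(name, corpus, aff, t, long_w=24, short_w=6):
    """Recompute one feature value the slow way."""
    t = pd.Timestamp(t)
    if name in ("late_transfer_ratio", "late_processing_ratio", "late_disposal_ratio"):
        fld = {
            "late_transfer_ratio": "transferred_late",
            "late_processing_ratio": "processed_late",
            "late_disposal_ratio": "disposed_late",
        }[name]
        known = [
            getattr(r, fld)
            for r in _window_cases(corpus, aff, t, long_w)
            if not pd.isna(getattr(r, fld))
        ]
        return _ratio(sum(bool(v) for v in known), len(known))
    if name == "invalidated_ae_ratio":
        wc = _window_cases(corpus, aff, t, long_w)
        return _ratio(sum(bool(r.invalidated) for r in wc), len(wc))
    if name == "qc_updated_ratio":
        wc = _window_cases(corpus, aff, t, long_w)
        return _ratio(sum(bool(r.qc_updated) for r in wc), len(wc))
    if name == "key_attr_correction_ratio":
        wc = _window_cases(corpus, aff, t, long_w)
        return _ratio(sum(1 for r in wc if r.key_attr_corrections != ""), len(wc))
    if name == "late_submission_ratio":
        subs = [
            s for s in _window_subs(corpus, aff, t, long_w) if bool(s.submitted)
        ]
        return _ratio(sum(1 for s in subs if int(s.days_late) > 0), len(subs))
    if name in ("unjustified_nonsubmission_ha_ratio", "unjustified_nonsubmission_lp_ratio"):
        dest = "health_authority" if name.endswith("ha_ratio") else "license_partner"
        subs = [
            s
            for s in _window_subs(corpus, aff, t, long_w)
            if s.destination == dest and not bool(s.submitted)
        ]
        num = sum(1 for s in subs if not pd.isna(s.justified_nonsubmission) and not bool(s.justified_nonsubmission))
        return _ratio(num, len(subs))
    if name == "active_studies_no_ae_ratio":
        lo = sub_months(t, long_w)
        active = [
            r
            for r in corpus.studies.itertuples(index=False)
            if r.affiliate_id == aff
            and r.start_date < t
            and (pd.isna(r.end_date) or r.end_date >= lo)
        ]
        wc = _window_cases(corpus, aff, t, long_w)
        no_ae = 0
        for st in active:
            n_ae = sum(
                1 for c in wc if not pd.isna(c.study_id) and c.study_id == st.study_id
            )
            if n_ae == 0:
                no_ae += 1
        return _ratio(no_ae, len(active))
    if name.startswith("source_share_"):
        src = name[len("source_share_") :]
        wc = _window_cases(corpus, aff, t, long_w)
        return _ratio(sum(1 for r in wc if r.primary_source == src), len(wc))
    if name.startswith("days_late_q"):
        q = int(name[len("days_late_q") :]) / 100.0
        subs = [
            s for s in _window_subs(corpus, aff, t, long_w) if bool(s.submitted)
        ]
        return _nearest_rank([int(s.days_late) for s in subs if not pd.isna(s.days_late)], q)
    if name == "ae_sales_rate_change":
        def rate(w):
            lo = sub_months(t, w)
            ae = len(_window_cases(corpus, aff, t, w))
            sales = sum(
                r.units_sold
                for r in corpus.sales.itertuples(index=False)
                if r.affiliate_id == aff and lo <= r.month < t
            )
            return NAN if sales == 0 else ae / sales

        r_long, r_short = rate(long_w), rate(short_w)
        if math.isnan(r_long) or math.isnan(r_short) or r_long == 0:
            return NAN
        return r_short / r_long
    raise KeyError(name)


def newton_raphson_logistic(X: np.ndarray, y: np.ndarray, iters: int = 50) -> np.ndarray:
    """Textbook unregularized Newton-Raphson MLE on a design with an
    explicit intercept column."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None])
        beta = beta + np.linalg.solve(H, grad)
        if np.max(np.abs(grad)) < 1e-12:
            break
    return beta
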