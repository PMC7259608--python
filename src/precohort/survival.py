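"""Comparative overall survival within a precision cohort.

Once a precision cohort is trimmed to patients resembling the index case,
treatment arms are compared on overall survival with the Kaplan–Meier
product-limit estimator: follow-up runs from each patient's index date to
death, or to the end of the observation window for survivors
(administrative censoring).  The comparison is graphical — two step curves
per chart — matching how a clinician would weigh the arms; optional
Greenwood confidence bands and a log-rank test are available for users who
want them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .claims import ClaimsDataset

SURVIVAL_COLUMNS = ["ID", "TIME", "EVENT", "ARM"]


@dataclass
class KMCurve:
    """Product-limit survival curve for one treatment arm.

    Arrays are aligned over the distinct observed times (events and
    censorings): ``survival[i]`` is the estimate just after ``times[i]``;
    ``n_risk[i]`` and ``n_events[i]`` are the at-risk and death counts at
    that time.  Estimates start at 1 and are non-increasing.
    """

    arm: str
    times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray  # Greenwood variance of the estimate

    def survival_at(self, t: float) -> float:
        """S(t): the step-function value at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def derive_survival_records(dataset: ClaimsDataset, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-patient follow-up time, event indicator and treatment arm.

    ``TIME`` is days from index to death (``EVENT`` True) or to the end of
    the observation window (``EVENT`` False).  A death before index is a
    data error — such patients should have been excluded upstream.
    """
    ins = dataset.insurants.set_index("ID")
    death = cohort["ID"].map(ins["DATEOFDEATH"])
    if (death.notna() & (death < cohort["DATEIndex"])).any():
        bad = cohort.loc[death.notna() & (death < cohort["DATEIndex"]), "ID"].tolist()
        raise ValueError(f"death before index for patients {bad[:5]}")
    window_end = dataset.observation_window[1]
    event = death.notna()
    end = death.fillna(window_end)
    return pd.DataFrame({
        "ID": cohort["ID"].to_numpy(),
        "TIME": (end - cohort["DATEIndex"]).dt.days.to_numpy(),
        "EVENT": event.to_numpy(),
        "ARM": cohort["TREATMENT"].to_numpy(),
    })


def km_estimate(records: pd.DataFrame, arm: str | None = None) -> KMCurve:
    """Kaplan–Meier product-limit estimate for one arm's records.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over the distinct death
    times ``t_i``; individuals censored at an event time stay at risk for
    it (deaths processed before censorings on ties, the standard
    convention).  Greenwood's formula supplies the variance.
    """
    if arm is not None:
        records = records[records["ARM"] == arm]
    if records.empty:
        raise ValueError("no survival records for the requested arm")
    label = arm if arm is not None else str(records["ARM"].iloc[0])

    times = records["TIME"].to_numpy(dtype=float)
    events = records["EVENT"].to_numpy(dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    uniq = np.unique(times)
    n = len(times)
    surv, var_sum = 1.0, 0.0
    s_list, nrisk_list, d_list, var_list = [], [], [], []
    for t in uniq:
        at_risk = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        if d > 0:
            surv *= 1.0 - d / at_risk
            if at_risk > d:
                var_sum += d / (at_risk * (at_risk - d))
        s_list.append(surv)
        nrisk_list.append(at_risk)
        d_list.append(d)
        var_list.append(surv * surv * var_sum)
    return KMCurve(
        arm=label,
        times=uniq,
        survival=np.asarray(s_list),
        n_risk=np.asarray(nrisk_list),
        n_events=np.asarray(d_list),
        variance=np.asarray(var_list),
    )


def km_by_arm(records: pd.DataFrame) -> list[KMCurve]:
    """One Kaplan–Meier curve per treatment arm, arms in sorted order."""
    return [km_estimate(records, arm) for arm in sorted(records["ARM"].unique())]


def curve_table(curve: KMCurve) -> pd.DataFrame:
    """The curve as a tidy table (one row per distinct time)."""
    return pd.DataFrame({
        "ARM": curve.arm,
        "TIME": curve.times,
        "SURVIVAL": curve.survival,
        "N_RISK": curve.n_risk,
        "N_EVENTS": curve.n_events,
    })


def plot_km(
    curves: list[KMCurve],
    output: str | Path,
    title: str | None = None,
    confidence_bands: bool = False,
) -> Path:
    """Step-function survival plot, one trace per arm, with at-risk counts."""
    if not curves:
        raise ValueError("need at least one curve to plot")
    fig, ax = plt.subplots(figsize=(7, 5))
    for curve in curves:
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        (line,) = ax.step(t, s, where="post", label=f"{curve.arm} (n={curve.n_risk[0]})")
        if confidence_bands:
            se = np.sqrt(np.concatenate([[0.0], curve.variance]))
            ax.fill_between(t, np.clip(s - 1.96 * se, 0, 1),
                            np.clip(s + 1.96 * se, 0, 1),
                            step="post", alpha=0.2, color=line.get_color())
    ax.set_xlabel("days since index")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    output = Path(output)
    output.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(output, dpi=150)
    plt.close(fig)
    return output


def logrank_test(records: pd.DataFrame):
    """Two-sample log-rank test between the arms (optional extra).

    Thin wrapper around :mod:`lifelines`; returns its result object.  The
    core workflow compares arms graphically and does not require this.
    """
    from lifelines.statistics import logrank_test as _lr

    arms = sorted(records["ARM"].unique())
    if len(arms) != 2:
        raise ValueError(f"log-rank needs exactly two arms, got {arms}")
    a = records[records["ARM"] == arms[0]]
    b = records[records["ARM"] == arms[1]]
    return _lr(a["TIME"], b["TIME"], event_observed_A=a["EVENT"],
               event_observed_B=b["EVENT"])
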