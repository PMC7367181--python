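"""Event-level cytometry statistics: gating, per-replicate moments, control normalization.

An event table is a tidy frame with one fluorescence intensity per cell and
columns ``construct_id``, ``replicate``, ``intensity``.  Two reserved
construct ids carry the calibration samples: ``"control"`` (the no-sgRNA
strain used to normalize means) and ``"blank"`` (fixative only, used to set
the gating threshold).

For single-channel data the scatter gate of a cytometer is replaced by an
intensity threshold at an upper quantile of the blank; expression noise is
``eta^2 = sigma^2 / mu^2`` with the sample (n-1) standard deviation, and it
is invariant under the control normalization of the mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import (
    GatingWarning,
    InsufficientDataError,
    NormalizationError,
    UndefinedNoiseError,
)

__all__ = [
    "CONTROL_ID",
    "BLANK_ID",
    "EVENT_COLUMNS",
    "validate_events",
    "gate_events",
    "summarize",
    "normalize_to_control",
    "read_events_csv",
    "write_events_csv",
]

CONTROL_ID = "control"
BLANK_ID = "blank"
EVENT_COLUMNS = ("construct_id", "replicate", "intensity")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise InsufficientDataError(f"event table is missing columns {missing}")
    if not np.isfinite(events["intensity"].to_numpy(dtype=float)).all():
        raise InsufficientDataError("event intensities must be finite")
    return events


def gate_events(
    events: pd.DataFrame,
    blank: pd.DataFrame | None,
    quantile: float = 0.99,
) -> pd.DataFrame:
    """Remove events at or below the blank's upper-quantile intensity.

    The threshold is fixed by the blank alone, so gating is idempotent.  A
    warning is emitted if any (construct, replicate) group loses more than
    half its events, or if the blank is empty (gating disabled,
    pass-through).
    """
    validate_events(events)
    if blank is None or len(blank) == 0:
        warnings.warn("empty blank: gating disabled, passing events through",
                      GatingWarning, stacklevel=2)
        return events.copy()
    threshold = float(np.quantile(blank["intensity"].to_numpy(dtype=float), quantile))
    kept = events[events["intensity"] > threshold]
    before = events.groupby(["construct_id", "replicate"], sort=False).size()
    after = kept.groupby(["construct_id", "replicate"], sort=False).size()
    frac = (after.reindex(before.index, fill_value=0) / before).min()
    if frac < 0.5:
        warnings.warn(
            f"gating removed more than half the events of at least one group "
            f"(worst survival {frac:.1%}) at threshold {threshold:g}",
            GatingWarning,
            stacklevel=2,
        )
    return kept.reset_index(drop=True)


def summarize(events: pd.DataFrame) -> pd.DataFrame:
    """Per-(construct, replicate) mean, sd, and noise eta^2 = sd^2/mean^2.

    Uses the sample (n-1) standard deviation.  Requires at least two events
    and a positive mean per group.
    """
    validate_events(events)
    if events.empty:
        raise InsufficientDataError("no events to summarize")
    rows = []
    for (cid, rep), grp in events.groupby(["construct_id", "replicate"], sort=True):
        x = grp["intensity"].to_numpy(dtype=float)
        if x.size < 2:
            raise InsufficientDataError(
                f"group ({cid!r}, {rep}) has {x.size} event(s); need >= 2"
            )
        mu = float(x.mean())
        if mu <= 0:
            raise UndefinedNoiseError(f"group ({cid!r}, {rep}) has non-positive mean")
        sd = float(x.std(ddof=1))
        rows.append(
            {
                "construct_id": cid,
                "replicate": rep,
                "n_events": int(x.size),
                "mu": mu,
                "sigma": sd,
                "eta2": (sd / mu) ** 2,
            }
        )
    return pd.DataFrame(rows)


def normalize_to_control(
    summaries: pd.DataFrame,
    control_id: str = CONTROL_ID,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Attach ``norm_mean = mu/mu_control`` and its inverse.

    ``mode="pooled"`` divides by the control mean pooled over replicates;
    ``mode="replicate"`` divides replicate-wise (each replicate by its own
    control replicate).  Noise is untouched: eta^2 is scale-invariant.
    """
    if mode not in ("pooled", "replicate"):
        raise NormalizationError(f"unknown normalization mode {mode!r}")
    ctrl = summaries[summaries["construct_id"] == control_id]
    if ctrl.empty:
        raise NormalizationError(f"no {control_id!r} rows found for normalization")
    out = summaries.copy()
    if mode == "pooled":
        mu_c = float(ctrl["mu"].mean())
        if mu_c <= 0:
            raise NormalizationError("control mean must be positive")
        out["norm_mean"] = out["mu"] / mu_c
    else:
        mu_by_rep = ctrl.set_index("replicate")["mu"]
        missing = set(out["replicate"]) - set(mu_by_rep.index)
        if missing:
            raise NormalizationError(f"control is missing replicates {sorted(missing)}")
        out["norm_mean"] = out["mu"] / out["replicate"].map(mu_by_rep)
    out["inv_norm_mean"] = 1.0 / out["norm_mean"]
    return out


def read_events_csv(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf)
    return validate_events(df)


def write_events_csv(events: pd.DataFrame, path_or_buf) -> None:
    validate_events(events)
    events.to_csv(path_or_buf, index=False, float_format="%.12g")
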