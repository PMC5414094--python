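"""ChIP-qPCR percent-of-input and RT-qPCR relative expression.

Both quantities assume perfect amplification efficiency (a factor of 2
per cycle).  Percent of input adjusts the input aliquot's Ct to a 100%
equivalent before comparing with the IP:

    %input = 100 * 2^[(Ct_input - log2(1/f)) - Ct_IP]

where ``f`` is the fraction of chromatin used for the input aliquot.
Relative expression is the standard 2^(-ddCt) with a reference gene per
condition.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QPCRMeasurement:
    """One ChIP-qPCR target: IP and input Ct plus the input aliquot fraction."""

    target_label: str
    ct_ip: float
    ct_input: float
    input_fraction: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        for name, ct in (("ct_ip", self.ct_ip), ("ct_input", self.ct_input)):
            if not (math.isfinite(ct) and ct > 0):
                raise ValueError(f"{name} must be positive and finite")
        if not 0 < self.input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ExpressionMeasurement:
    """Target and reference Ct for one gene in one condition."""

    gene: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_reference):
            if not (math.isfinite(ct) and ct > 0):
                raise ValueError("cycle thresholds must be positive and finite")


def percent_input(m: QPCRMeasurement) -> float:
    """Immunoprecipitated DNA as a percentage of the chromatin input."""
    adjusted_input = m.ct_input - math.log2(1.0 / m.input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - m.ct_ip)


def aggregate_percent_input(
    measurements: Iterable[QPCRMeasurement],
) -> pd.DataFrame:
    """Mean +/- s.d. of percent-of-input across replicates per target."""
    rows = [
        {"target": m.target_label, "replicate": m.replicate_id, "percent_input": percent_input(m)}
        for m in measurements
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no measurements")
    out = (
        df.groupby("target", sort=False)["percent_input"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="count")
        .reset_index()
    )
    return out


def relative_expression(
    treated: ExpressionMeasurement, control: ExpressionMeasurement
) -> float:
    """Fold change by 2^(-ddCt), reference-gene normalised per condition."""
    dct_treated = treated.ct_target - treated.ct_reference
    dct_control = control.ct_target - control.ct_reference
    return 2.0 ** -(dct_treated - dct_control)


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a long-format plate CSV: sample, target, ct, role.

    ``role`` is "ip" or "input" for ChIP-qPCR rows, "target" or
    "reference" for expression rows.
    """
    df = pd.read_csv(path)
    required = {"sample", "target", "ct", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["role"] = df["role"].str.lower()
    return df


def percent_input_from_plate(
    path: str | Path, input_fraction: float
) -> pd.DataFrame:
    """Percent-of-input per (sample, target) from a plate CSV.

    Pairs each "ip" row with the "input" row of the same sample and
    target; replicates are averaged after the per-replicate transform.
    """
    df = read_plate(path)
    out_rows = []
    for (sample, target), grp in df.groupby(["sample", "target"], sort=False):
        ips = grp[grp["role"] == "ip"]["ct"].to_numpy()
        inputs = grp[grp["role"] == "input"]["ct"].to_numpy()
        if len(ips) == 0 or len(inputs) == 0:
            continue
        n = min(len(ips), len(inputs))
        vals = [
            percent_input(
                QPCRMeasurement(target, float(ip), float(inp), input_fraction, str(i))
            )
            for i, (ip, inp) in enumerate(zip(ips[:n], inputs[:n]))
        ]
        out_rows.append(
            {
                "sample": sample,
                "target": target,
                "percent_input_mean": float(np.mean(vals)),
                "percent_input_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            }
        )
    if not out_rows:
        raise ValueError("no ip/input pairs found in plate")
    return pd.DataFrame(out_rows)
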