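"""Relative quantification of ChIP-/DRIP-qPCR with input and spike-in
normalisation, plus the treated-vs-control replicate scaling and the
one-tailed unpaired t-test used for significance.

Cq table layout (tab-separated): sample_id, condition, replicate, target,
role, cq.  Roles are IP, input, IgG and spike_in.  For spike_in rows the
``target`` field names the compartment of the spike amplicon ("IP" or
"input"), since the foreign-genome spike amplicon is measured in both the
IP and the input material of every sample.

Quantification algebra (amplification efficiency E, default 2 = perfect
doubling): the input Cq is first shifted by log_E(1/input_fraction) to
represent the whole input (10% taken as input shifts by log2(10) ~ 3.32
cycles), then

    enrichment = E ** (adjusted input Cq - IP Cq)            (percent input)

and, when a spike-in is present, the target's percent input is divided by
the spike amplicon's percent input (ratio of ratios), cancelling sample-to-
sample IP-efficiency differences.  IgG rows are carried through for
reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, FormatError, ParameterError, SchemaError
from .simulate import CQ_COLUMNS, CQ_ROLES

#: significance annotation thresholds (P <= threshold, checked in order)
STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def read_cq(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_cq(df)


def write_cq(table: pd.DataFrame, path) -> None:
    validate_cq(table).to_csv(path, sep="\t", index=False)


def validate_cq(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CQ_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"Cq table missing columns: {missing}")
    bad_roles = set(table["role"]) - set(CQ_ROLES)
    if bad_roles:
        raise SchemaError(f"unknown Cq roles: {sorted(bad_roles)}")
    cq = pd.to_numeric(table["cq"], errors="coerce")
    if cq.isna().any() or not np.isfinite(cq).all() or (cq <= 0).any():
        raise DataError("Cq values must be finite and > 0")
    return table


def percent_input(
    table: pd.DataFrame,
    efficiency: float = 2.0,
    input_fraction: float = 0.1,
) -> pd.DataFrame:
    """Per-(condition, replicate) enrichment over input, spike-normalised.

    Returns a frame with condition, replicate, enrichment,
    igg_percent_input (NaN when absent) and spike_normalized flag.
    """
    if efficiency <= 1:
        raise ParameterError(f"efficiency must be > 1, got {efficiency}")
    if not 0 < input_fraction <= 1:
        raise ParameterError(f"input_fraction must be in (0, 1], got {input_fraction}")
    validate_cq(table)
    adjust = math.log(1.0 / input_fraction) / math.log(efficiency)
    rows = []
    for (cond, rep), block in table.groupby(["condition", "replicate"], sort=False):
        def one_cq(mask, what):
            sel = block.loc[mask, "cq"]
            if len(sel) == 0:
                raise SchemaError(
                    f"({cond}, {rep}): missing {what} measurement"
                )
            return float(sel.mean())

        roles = block["role"]
        ip = one_cq(roles == "IP", "IP")
        inp = one_cq(roles == "input", "input")
        enr = efficiency ** ((inp - adjust) - ip)
        spike = roles == "spike_in"
        spiked = bool(spike.any())
        if spiked:
            sp_ip = one_cq(spike & (block["target"] == "IP"), "spike_in IP")
            sp_in = one_cq(spike & (block["target"] == "input"), "spike_in input")
            enr /= efficiency ** ((sp_in - adjust) - sp_ip)
        igg = np.nan
        if (roles == "IgG").any():
            igg = efficiency ** ((inp - adjust) - one_cq(roles == "IgG", "IgG"))
        rows.append((cond, rep, enr, igg, spiked))
    return pd.DataFrame(
        rows,
        columns=["condition", "replicate", "enrichment", "igg_percent_input",
                 "spike_normalized"],
    )


def scale_to_control(
    values: pd.DataFrame,
    control_condition: str = "untreated",
    value_col: str = "enrichment",
) -> pd.DataFrame:
    """Two-step scaling of matched treated/control sets.

    Step 1: within each replicate, divide every value by that replicate's
    mean across its samples.  Step 2: divide all values by the mean of the
    control-condition values, so the control mean is exactly 1.
    """
    if control_condition not in set(values["condition"]):
        raise DataError(f"no {control_condition!r} samples to scale to")
    out = values.copy()
    vals = out[value_col].astype(float)
    if (vals <= 0).any():
        raise DataError("relative quantities must be positive")
    rep_means = vals.groupby(out["replicate"]).transform("mean")
    scaled = vals / rep_means
    ctrl_mean = scaled[out["condition"] == control_condition].mean()
    out["scaled"] = scaled / ctrl_mean
    return out


def one_tailed_ttest(group_a, group_b) -> tuple[float, float, str]:
    """Unpaired pooled-variance t-test, one-tailed in the direction of the
    observed mean difference.

    Returns (t statistic, one-tailed P, significance stars).  Equal means
    give t = 0 and P = 0.5.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs >= 2 values")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        t = 0.0 if a.mean() == b.mean() else math.inf * np.sign(a.mean() - b.mean())
    else:
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = float(stats.t.sf(abs(t), na + nb - 2))
    return float(t), p, significance_stars(p)


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_LEVELS:
        if p <= threshold:
            return stars
    return "n.s."


@dataclass
class RelquantModel:
    """qPCR relative quantification over a Cq table.

    ``fit()`` runs percent-input (+ spike-in) quantification and the
    treated-vs-control scaling, and tests each treated condition against
    the control with the one-tailed unpaired t-test.
    """

    table: pd.DataFrame
    efficiency: float = 2.0
    input_fraction: float = 0.1
    control_condition: str = "untreated"

    @classmethod
    def from_file(cls, path, **kwargs) -> "RelquantModel":
        return cls(read_cq(path), **kwargs)

    def fit(self) -> "RelquantResults":
        per_sample = percent_input(
            self.table, efficiency=self.efficiency,
            input_fraction=self.input_fraction,
        )
        scaled = scale_to_control(
            per_sample, control_condition=self.control_condition
        )
        tests = []
        ctrl = scaled.loc[scaled["condition"] == self.control_condition, "scaled"]
        for cond, block in scaled.groupby("condition", sort=False):
            if cond == self.control_condition:
                continue
            if len(block) >= 2 and len(ctrl) >= 2:
                t, p, star = one_tailed_ttest(block["scaled"], ctrl)
            else:
                t, p, star = np.nan, np.nan, ""
            tests.append((cond, block["scaled"].mean(), t, p, star))
        test_table = pd.DataFrame(
            tests, columns=["condition", "mean_scaled", "t", "one_tailed_p", "stars"]
        )
        return RelquantResults(model=self, sample_table=scaled, test_table=test_table)


@dataclass
class RelquantResults:
    model: RelquantModel
    sample_table: pd.DataFrame
    test_table: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "qPCR relative quantification",
            f"  efficiency {self.model.efficiency:g}, input fraction "
            f"{self.model.input_fraction:g}, control = "
            f"{self.model.control_condition!r}",
            "",
            self.sample_table.to_string(index=False),
        ]
        if len(self.test_table):
            lines += ["", self.test_table.to_string(index=False)]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.sample_table.to_csv(path, sep="\t", index=False)
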