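"""Expression quantification: FPKM and efficiency-corrected RT-qPCR ratios.

The qPCR model is the standard efficiency-corrected relative quantification:
each gene's amplification efficiency E (fold increase per cycle; E = 2 is
perfect doubling) is estimated from a serial-dilution calibration curve as
E = 10^(-1/slope), where the slope comes from an ordinary least-squares fit
of Cp against log10(dilution).  The relative amount of a target gene versus
a reference gene (e.g. actin) in one cDNA is then

    ratio = E_ref ** Cp_ref / E_target ** Cp_target

evaluated in log space.  A calibrator sample measured in every run corrects
multiplicative run-to-run variation.  Replicate structure: each RNA is
reverse-transcribed in independent RT reactions and each cDNA measured in
technical duplicates; technical replicates are averaged on the Cp scale
within an RT replicate, one ratio is formed per RT replicate (pairing
target and reference within the same physical cDNA cancels loading
variation), and the reported value is the mean +/- sd over RT replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CpTable

__all__ = [
    "CalibrationCurve",
    "ExpressionRatio",
    "fit_calibration",
    "relative_ratio",
    "calibrator_normalize",
    "aggregate_sample",
    "cdna_rescale",
    "fpkm",
]

# Above this the chemistry would outperform perfect doubling by >10%;
# flagged as suspicious but not an error (the math stays total up to 4).
EFFICIENCY_WARN = 2.2
EFFICIENCY_MAX = 4.0


@dataclass(frozen=True)
class CalibrationCurve:
    """A Cp-vs-log10(dilution) standard curve for one gene."""

    gene_id: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    n_points: int
    valid: bool = True


@dataclass(frozen=True)
class ExpressionRatio:
    sample_id: str
    gene_id: str
    ratio: float
    sd: float
    n_rt_replicates: int
    normalization: str = "actin"


def fit_calibration(
    dilutions: list[float], cps: list[float], gene_id: str = ""
) -> CalibrationCurve:
    """Fit a dilution-series calibration curve and derive the efficiency.

    Requires >= 3 distinct dilution factors.  A non-negative slope means no
    amplification signal: the curve is returned with ``valid=False`` and an
    efficiency of NaN.
    """
    if len(dilutions) != len(cps):
        raise ValueError("dilutions and cps must have equal length")
    if any(d <= 0 for d in dilutions):
        raise ValueError("dilution factors must be positive")
    if len(set(dilutions)) < 3:
        raise ValueError("need at least 3 distinct dilutions")
    x = np.log10(np.asarray(dilutions, dtype=float))
    y = np.asarray(cps, dtype=float)
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r_squared = float(fit.rvalue**2)
    if slope >= 0:
        return CalibrationCurve(
            gene_id, slope, intercept, float("nan"), r_squared, len(x), valid=False
        )
    efficiency = 10.0 ** (-1.0 / slope)
    return CalibrationCurve(gene_id, slope, intercept, efficiency, r_squared, len(x))


def relative_ratio(
    e_ref: float, cp_ref: float, e_target: float, cp_target: float
) -> float:
    """Efficiency-corrected relative expression: E_ref^Cp_ref / E_target^Cp_target."""
    for e in (e_ref, e_target):
        if not 1.0 < e <= EFFICIENCY_MAX:
            raise ValueError(f"efficiency {e} outside (1, {EFFICIENCY_MAX}]")
    if cp_ref <= 0 or cp_target <= 0:
        raise ValueError("Cp values must be positive")
    log_ratio = cp_ref * math.log(e_ref) - cp_target * math.log(e_target)
    ratio = math.exp(log_ratio)
    if not math.isfinite(ratio):
        raise ArithmeticError("relative ratio overflowed")
    return ratio


def calibrator_normalize(
    sample_ratio: float,
    calibrator_ratio_this_run: float,
    calibrator_ratio_reference_run: float,
) -> float:
    """Correct a ratio for run-to-run variation via the shared calibrator sample."""
    vals = (sample_ratio, calibrator_ratio_this_run, calibrator_ratio_reference_run)
    if any(v <= 0 for v in vals):
        raise ValueError("all ratios must be positive")
    return sample_ratio * calibrator_ratio_reference_run / calibrator_ratio_this_run


def _rt_ratios(
    meas, sample_id: str, gene_id: str, curves, reference_gene: str
) -> list[tuple[str, float]]:
    """One efficiency-corrected ratio per (run, RT replicate) for a sample/gene."""
    e_t = curves[gene_id].efficiency
    e_r = curves[reference_gene].efficiency
    gene_rows = meas[(meas["sample_id"] == sample_id) & (meas["gene_id"] == gene_id)]
    out: list[tuple[str, float]] = []
    for (run, rt), grp in gene_rows.groupby(["run_id", "rt_replicate"], sort=True):
        cp_t = float(grp["cp"].mean())
        ref_rows = meas[
            (meas["sample_id"] == sample_id)
            & (meas["gene_id"] == reference_gene)
            & (meas["run_id"] == run)
            & (meas["rt_replicate"] == rt)
        ]
        if ref_rows.empty:
            raise ValueError(
                f"no reference-gene ({reference_gene!r}) Cp for sample "
                f"{sample_id!r}, run {run!r}, RT replicate {rt!r}"
            )
        cp_r = float(ref_rows["cp"].mean())
        out.append((str(run), relative_ratio(e_r, cp_r, e_t, cp_t)))
    return out


def aggregate_sample(
    cp_table: CpTable,
    curves: dict[str, CalibrationCurve],
    reference_gene: str,
) -> list[ExpressionRatio]:
    """Aggregate a Cp table into per-sample, per-gene expression ratios.

    Technical replicates are averaged on the Cp scale within each RT
    replicate; a ratio against the matched reference-gene Cp (same sample,
    run and RT replicate) is formed per RT replicate; run-to-run variation
    is removed with the calibrator sample when present (the reference run is
    the lexicographically first run); the result is mean +/- sd (ddof=1)
    across RT replicates.
    """
    meas = cp_table.measurements()
    genes = sorted(set(meas["gene_id"]) - {reference_gene})
    for g in genes + [reference_gene]:
        if g not in curves:
            raise ValueError(f"no calibration curve for gene {g!r}")
        if not curves[g].valid:
            raise ValueError(f"invalid calibration curve for gene {g!r}")

    cal_rows = meas[meas["role"] == "calibrator"]
    cal_samples = sorted(set(cal_rows["sample_id"]))
    runs = sorted(set(meas["run_id"].astype(str)))
    reference_run = runs[0]

    # per (gene, run): calibrator ratio, averaged over the calibrator's RT reps
    acc: dict[tuple[str, str], list[float]] = {}
    for cal_sample in cal_samples:
        for gene in genes:
            for run, r in _rt_ratios(meas, cal_sample, gene, curves, reference_gene):
                acc.setdefault((gene, run), []).append(r)
    cal_ratio = {k: float(np.mean(v)) for k, v in acc.items()}

    results: list[ExpressionRatio] = []
    target_rows = meas[meas["role"] == "target"]
    for sample_id in sorted(set(target_rows["sample_id"])):
        for gene in genes:
            sub = target_rows[
                (target_rows["sample_id"] == sample_id)
                & (target_rows["gene_id"] == gene)
            ]
            if sub.empty:
                continue
            ratios = []
            for run, r in _rt_ratios(meas, sample_id, gene, curves, reference_gene):
                if (gene, run) in cal_ratio and (gene, reference_run) in cal_ratio:
                    r = calibrator_normalize(
                        r, cal_ratio[(gene, run)], cal_ratio[(gene, reference_run)]
                    )
                ratios.append(r)
            arr = np.asarray(ratios, dtype=float)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            results.append(
                ExpressionRatio(
                    sample_id=sample_id,
                    gene_id=gene,
                    ratio=float(arr.mean()),
                    sd=sd,
                    n_rt_replicates=len(arr),
                )
            )
    return results


def cdna_rescale(
    ratios_cdna_normalized: list[float],
    bridge_samples: list[tuple[float, float]],
) -> list[float]:
    """Bridge cDNA-normalized ratios into reference-gene-normalized space.

    Used when the reference gene is unusable in some material (e.g. its
    expression is too low in seeds): those samples are normalized by cDNA
    amount instead, then rescaled by the geometric mean, over bridge samples
    measured both ways, of (reference-normalized / cDNA-normalized).
    """
    if not bridge_samples:
        raise ValueError("need at least one bridge sample")
    if any(v <= 0 for v in ratios_cdna_normalized):
        raise ValueError("ratios must be positive")
    if any(c <= 0 or a <= 0 for c, a in bridge_samples):
        raise ValueError("bridge values must be positive")
    log_factor = float(
        np.mean([math.log(a) - math.log(c) for c, a in bridge_samples])
    )
    factor = math.exp(log_factor)
    return [r * factor for r in ratios_cdna_normalized]


def fpkm(
    fragments: float, transcript_length: int, total_mapped_fragments: int
) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if transcript_length <= 0:
        raise ValueError("transcript_length must be positive")
    if total_mapped_fragments <= 0:
        raise ValueError("total_mapped_fragments must be positive")
    if fragments < 0:
        raise ValueError("fragment count cannot be negative")
    return fragments / ((transcript_length / 1e3) * (total_mapped_fragments / 1e6))
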