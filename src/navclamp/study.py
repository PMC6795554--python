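"""Study orchestration: simulate cohorts, extract features, write per-cell
tables and group summaries.  Outputs are pure functions of (config, seeds):
no wall-clock state enters any file, so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .channel import Genotype, load_genotype
from .clamp import build_protocol, run_oocyte_protocol, run_protocol
from .cohorts import (default_hek_spec, default_oocyte_spec,
                      generate_hek_cohort, generate_oocyte_cohort)
from .features import extract_cell
from .gatingpore import correlate_gp_qmax, extract_oocyte
from .targets import REPORTED

__all__ = ["RunConfig", "run_study", "simulate_hek_cohort", "simulate_oocyte_cohort"]


class RunConfig(BaseModel):
    """Configuration for one full reproducible run.

    Seeds are explicit (never wall clock).  ``hek_n``/``oocyte_n`` override
    the default group sizes (useful for quick runs); protocols lists which
    HEK protocols to run per cell.
    """

    model_config = ConfigDict(frozen=True)

    genotypes: tuple[Genotype, ...] = (Genotype.WT, Genotype.R1882Q, Genotype.R853Q)
    seed: int = 1
    hek_n: int | None = None
    oocyte_n: int | None = None
    hek_noise_sd: float = 2.5
    oocyte_correlation_n: int | None = None
    protocols: tuple[str, ...] = ("activation_iv", "inactivation", "resurgent")
    include_oocytes: bool = True
    out_dir: str = "results/study"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if len(self.genotypes) == 0:
            raise ValueError("genotypes list must not be empty")
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def simulate_hek_cohort(genotype: Genotype | str, seed: int, n: int | None = None,
                        noise_sd: float = 2.5,
                        protocols=("activation_iv", "inactivation", "resurgent")):
    """Simulate one HEK cohort and extract per-cell features.

    Returns (list of ExtractionReport, DataFrame of feature rows).
    """
    g = Genotype(genotype)
    spec = default_hek_spec(g, seed=seed, n=n)
    spec = spec.model_copy(update={"noise_sd": noise_sd})
    cells = generate_hek_cohort(spec)
    params = load_genotype(g)
    prots = {name: build_protocol(name) for name in protocols}
    cell_seeds = _spawn_seeds(seed, len(cells) * len(prots))
    reports = []
    k = 0
    for idx, cell in enumerate(cells):
        runs = {}
        for name, prot in prots.items():
            runs[name] = run_protocol(cell, params, prot, seed=cell_seeds[k])
            k += 1
        rep = extract_cell(
            runs["activation_iv"],
            inact=runs.get("inactivation"),
            res=runs.get("resurgent"),
            Cm=cell.Cm, cell_id=f"{g.value}_c{idx:02d}",
        )
        reports.append(rep)
    df = pd.DataFrame([r.to_row() for r in reports])
    return reports, df


def simulate_oocyte_cohort(genotype: Genotype | str, seed: int, n: int | None = None,
                           correlation: bool = False):
    """Simulate one oocyte cohort through both protocols and extract the
    per-oocyte gating-charge / gating-pore report."""
    g = Genotype(genotype)
    spec = default_oocyte_spec(g, seed=seed, n=n, correlation=correlation)
    oocytes = generate_oocyte_cohort(spec)
    params = load_genotype(g)
    charge_prot = build_protocol("gating_charge")
    leak_prot = build_protocol("gp_leak")
    seeds = _spawn_seeds(seed, 2 * len(oocytes))
    reports = []
    for idx, oo in enumerate(oocytes):
        charge = run_oocyte_protocol(oo, params, charge_prot, seed=seeds[2 * idx])
        leak = run_oocyte_protocol(oo, params, leak_prot, seed=seeds[2 * idx + 1])
        reports.append(extract_oocyte(charge, leak, oocyte_id=f"{g.value}_oo{idx:02d}"))
    df = pd.DataFrame([r.to_row() for r in reports])
    return reports, df


def _summarize(df: pd.DataFrame) -> dict:
    out = {}
    num = df.select_dtypes(include=[np.number])
    n = len(df)
    for col in num.columns:
        vals = num[col].dropna()
        if not len(vals):
            continue
        out[col] = {"mean": float(vals.mean()),
                    "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                    "n": int(len(vals))}
    out["n_cells"] = n
    return out


def run_study(config: RunConfig) -> dict:
    """Simulate all configured cohorts, extract all features, and write
    per-cell CSVs, a group-summary JSON and a comparison table against the
    published group means.  Returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config": json.loads(config.model_dump_json()),
                  "config_hash": config.config_hash(), "seed": config.seed}
    seeds = _spawn_seeds(config.seed, 2 * len(config.genotypes) + 4)

    summary: dict = {"provenance": provenance, "hek": {}, "oocyte": {}}
    rows = []
    all_cells = []
    for i, g in enumerate(config.genotypes):
        _, df = simulate_hek_cohort(g, seed=seeds[i], n=config.hek_n,
                                    noise_sd=config.hek_noise_sd,
                                    protocols=config.protocols)
        all_cells.append(df)
        summary["hek"][g.value] = _summarize(df)
        for feature in ("act_v_half_mV", "inact_v_half_mV", "persistent_pct",
                        "resurgent_pct", "max_peak_pA"):
            reported_key = {
                "act_v_half_mV": "act_v_half_mV", "inact_v_half_mV": "inact_v_half_mV",
                "persistent_pct": "persistent_pct", "resurgent_pct": "resurgent_pct",
                "max_peak_pA": "max_peak_pA"}[feature]
            rep = REPORTED.get(g.value, {}).get(reported_key)
            if feature in df and rep is not None:
                rows.append({"genotype": g.value, "feature": feature,
                             "simulated_mean": float(df[feature].mean()),
                             "reported": rep})
    pd.concat(all_cells, ignore_index=True).to_csv(
        out / "hek_features.csv", index=False, float_format="%.6g")

    if config.include_oocytes:
        k = len(config.genotypes)
        oo_rows = []
        for j, g in enumerate([Genotype.WT, Genotype.R853Q]):
            if g not in config.genotypes:
                continue
            _, df = simulate_oocyte_cohort(g, seed=seeds[k + j], n=config.oocyte_n)
            oo_rows.append(df)
            summary["oocyte"][g.value] = _summarize(df)
            rep = REPORTED.get(g.value, {}).get("qmax_nC")
            if rep is not None:
                rows.append({"genotype": g.value, "feature": "qmax_nC",
                             "simulated_mean": float(df["qmax_nC"].mean()),
                             "reported": rep})
        if Genotype.R853Q in config.genotypes:
            _, df = simulate_oocyte_cohort(Genotype.R853Q, seed=seeds[-1],
                                           n=config.oocyte_correlation_n,
                                           correlation=True)
            corr = correlate_gp_qmax(df["qmax_nC"].to_numpy(),
                                     df["i_gp_m120_nA"].to_numpy())
            summary["oocyte"]["R853Q_correlation"] = {
                "slope_nA_per_nC": corr.slope, "pearson_r": corr.pearson_r,
                "r2_adj": corr.r2_adj, "n": corr.n}
            rows.append({"genotype": "R853Q", "feature": "gp_slope_nA_per_nC",
                         "simulated_mean": corr.slope,
                         "reported": REPORTED["R853Q"]["gp_slope_nA_per_nC"]})
            oo_rows.append(df)
        if oo_rows:
            pd.concat(oo_rows, ignore_index=True).to_csv(
                out / "oocyte_features.csv", index=False, float_format="%.6g")

    pd.DataFrame(rows).to_csv(out / "comparison.csv", index=False,
                              float_format="%.6g")
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
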