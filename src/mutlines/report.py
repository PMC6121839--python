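"""End-to-end orchestration: simulate -> call -> estimate -> spectrum -> pedigree.

:func:`run_all` executes the whole chain from a single :class:`RunConfig`
and writes a reproducible report bundle (TSV tables plus a machine-readable
JSON summary).  Identical config and seed produce byte-identical outputs:
all randomness flows from the config seed and no timestamps enter the files.

:func:`counts_report` is the counts-only entry point: it accepts a
Table-1-shaped per-line count file (line id, callable sites, category
counts), so published count tables can be turned into rate estimates without
any sequence data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dnmcall, io as mio, pedigree as ped, rates, simdata, spectrum

logger = logging.getLogger("mutlines")

__all__ = ["RunConfig", "run_all", "counts_report", "validate_summary"]


@dataclass
class RunConfig:
    """Parameters of a full simulated run (serializable to/from YAML)."""

    seed: int = 0
    out_dir: str = "mutlines_run"
    genome_length: int = 1_000_000
    at_content: float = 0.69
    n_scaffolds: int = 4
    pedigree: simdata.PedigreeConfig = field(
        default_factory=simdata.PedigreeConfig
    )
    thresholds: dnmcall.FilterThresholds = field(
        default_factory=dnmcall.FilterThresholds
    )
    mu_snm: float = 1e-5
    mu_ins: float = 2.5e-6
    mu_del: float = 5e-6
    ts_tv_kappa: float = simdata.DEFAULT_KAPPA
    run_affinity: float = simdata.DEFAULT_RUN_AFFINITY
    coverage_line: float = 25.0
    coverage_pool: float = 60.0
    error_rate: float = 0.0
    fp_shared: int = 0
    fp_error: int = 0
    pedigree_reps: int = 100_000
    write_fixture: bool = False

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["pedigree"] = simdata.PedigreeConfig(**d.get("pedigree", {}))
        d["thresholds"] = dnmcall.FilterThresholds(**d.get("thresholds", {}))
        return cls(**d)


SUMMARY_SCHEMA = {
    "seed": int,
    "n_true_mutations": int,
    "n_accepted": int,
    "sensitivity": float,
    "precision": float,
    "rates": dict,
    "spectrum_tests": dict,
    "pedigree": dict,
    "attrition": dict,
}


def validate_summary(summary: dict) -> None:
    """Check the summary JSON against its (flat) schema; raises on violation."""
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValueError(
                f"summary[{key!r}] has type {type(summary[key]).__name__}, "
                f"expected {typ.__name__}"
            )


def _estimate_json(est: rates.RateEstimate) -> dict:
    return {
        "count": est.count,
        "exposure": est.exposure,
        "rate": est.rate,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "method": est.method,
    }


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; write the report bundle; return the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    G = config.pedigree.n_generations

    logger.info("simulate: genome length %d, AT %.3f, seed %d",
                config.genome_length, config.at_content, rng_seed)
    genome = simdata.generate_genome(
        config.genome_length,
        simdata.BaseComposition.from_at_content(config.at_content),
        n_scaffolds=config.n_scaffolds,
        seed=rng_seed,
    )
    pedigree_cfg = dataclasses.replace(config.pedigree, seed=rng_seed)
    pedigree = simdata.simulate_pedigree(pedigree_cfg)
    truth = simdata.inject_mutations(
        pedigree, genome, config.mu_snm, config.mu_ins, config.mu_del,
        ts_tv_kappa=config.ts_tv_kappa, run_affinity=config.run_affinity,
        seed=rng_seed + 1,
    )
    rcs = simdata.render_callsets(
        pedigree, truth, genome,
        coverage_line=config.coverage_line, coverage_pool=config.coverage_pool,
        error_rate=config.error_rate, fp_shared=config.fp_shared,
        fp_error=config.fp_error, seed=rng_seed + 2,
    )
    if config.write_fixture:
        simdata.write_fixture(out / "fixture", genome, rcs)
    logger.info("simulate: %d true mutations, %d contaminant calls",
                len(truth), len(rcs.contaminants))

    result = dnmcall.run_pipeline(
        rcs.line_calls,
        rcs.pool_calls,
        {(s.scaffold, s.pos): s for s in rcs.pool_sites},
        rcs.depth_tracks,
        rcs.pool_depth_track,
        genome,
        config.thresholds,
    )
    accepted = result.accepted()
    truth_keys = {(m.line_id, *m.key) for m in rcs.truth}
    accepted_keys = {(m.line_id, *m.key) for m in accepted}
    tp = len(truth_keys & accepted_keys)
    sensitivity = tp / len(truth_keys) if truth_keys else 1.0
    precision = tp / len(accepted_keys) if accepted_keys else 1.0
    logger.info("call: %d accepted (sensitivity %.4f, precision %.4f)",
                len(accepted), sensitivity, precision)

    table, headline = rates.rate_table(accepted, result.callable, G)
    run_spec = spectrum.count_runs(genome)
    snm_recs = [m for m in accepted if m.mtype == "SNM"]
    spec_tests: dict[str, dict] = {}
    if snm_recs:
        ratio, ts, tv = spectrum.ts_tv_ratio(accepted)
        gc2at = sum(m.gc_at_direction == "GCtoAT" for m in snm_recs)
        at2gc = sum(m.gc_at_direction == "ATtoGC" for m in snm_recs)
        spec_tests["ts_tv"] = {"ratio": ratio, "ts": ts, "tv": tv}
        if gc2at + at2gc:
            t = spectrum.gof_equal_chi2(gc2at, at2gc)
            spec_tests["gc_at_bias"] = {
                "chi2": t.statistic, "p": t.p_value, "observed": list(t.observed)
            }
    n_ins = sum(m.mtype == "INS" for m in accepted)
    n_del = sum(m.mtype == "DEL" for m in accepted)
    if n_ins + n_del:
        t = spectrum.gof_equal_chi2(n_ins, n_del)
        spec_tests["ins_del_bias"] = {
            "chi2": t.statistic, "p": t.p_value, "observed": [n_ins, n_del]
        }
        enr = spectrum.run_enrichment_test(accepted, run_spec)
        spec_tests["run_enrichment"] = {
            "in_run": enr.observed[0], "total": sum(enr.observed),
            "expected_in_run": enr.expected[0], "p": enr.p_value,
        }
        rl_df, trend = spectrum.run_length_mutation_rate(
            accepted, run_spec, G, pedigree_cfg.n_lines
        )
        rl_df.to_csv(out / "run_length_rates.tsv", sep="\t", index=False)
        spec_tests["run_length_trend"] = {"rho": trend.rho, "p": trend.p_value}

    probs = ped.state_probabilities(
        pedigree_cfg, reps=config.pedigree_reps, seed=rng_seed + 3
    )
    frac, n_unconf = ped.expected_confirmable(G, len(accepted))
    p_confirm = float(
        ped.confirmation_probability(pedigree_cfg.n_confirm_siblings)
    )

    # --- write the bundle -------------------------------------------------
    table.to_csv(out / "rate_table.tsv", sep="\t")
    mio.write_mutations_tsv(out / "mutations.tsv", accepted)
    result.attrition.to_csv(out / "attrition.tsv", sep="\t")
    probs.as_frame().to_csv(out / "pedigree_probs.tsv", sep="\t")
    run_rows = []
    for cls in ("A", "C", "G", "T", "CpG"):
        for L, n in sorted(run_spec.counts[cls].items()):
            exp = spectrum.expected_run_density(
                run_spec.composition, cls, L
            ) * run_spec.genome_length / 1e6 if run_spec.composition else None
            run_rows.append({"class": cls, "length": L, "observed": n,
                             "expected_iid": exp})
    pd.DataFrame(run_rows).to_csv(out / "run_spectrum.tsv", sep="\t",
                                  index=False)

    summary = {
        "seed": rng_seed,
        "n_true_mutations": len(truth),
        "n_accepted": len(accepted),
        "sensitivity": sensitivity,
        "precision": precision,
        "rates": {k: _estimate_json(v) for k, v in headline.items()},
        "spectrum_tests": spec_tests,
        "pedigree": {
            "confirmable_fraction": frac,
            "expected_unconfirmable": n_unconf,
            "p_confirm_one_of_siblings": p_confirm,
            "p_hom_by_origin": [float(x) for x in probs.p_hom],
            "p_present_by_origin": [float(x) for x in probs.p_present],
        },
        "attrition": {
            line: {k: int(v) for k, v in row.items()}
            for line, row in result.attrition.iterrows()
        },
    }
    validate_summary(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def counts_report(
    counts: pd.DataFrame | str | Path,
    generations: int = 5,
    out_dir: str | Path | None = None,
    headline_ts_tv: tuple[int, int] | None = None,
    wald: bool = False,
) -> dict:
    """Rate report from a per-line count table alone (no sequence data).

    ``counts`` is a DataFrame or TSV path with columns ``line_id`` +
    :data:`mutlines.rates.COUNT_COLUMNS`.  ``headline_ts_tv`` optionally
    supplies the experiment-wide Ts/Tv counts when the per-line columns
    exclude multi-allelic sites (so the column sums undercount).
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.read_csv(counts, sep="\t", comment="#").set_index("line_id")
    table, headline = rates.rate_table_from_counts(counts, generations,
                                                   wald=wald)
    ts, tv = (
        headline_ts_tv
        if headline_ts_tv is not None
        else (int(counts["ts"].sum()), int(counts["tv"].sum()))
    )
    ratio, ts, tv = spectrum.ts_tv_from_counts(ts, tv)
    gc_at = None
    ins = int(counts["insertions"].sum())
    dele = int(counts["deletions"].sum())
    ins_del = spectrum.gof_equal_chi2(ins, dele)
    per_line = {
        line: rates.round_sig(float(r), 3)
        for line, r in table["mu"].items()
        if line != "SUM"
    }
    summary = {
        "generations": generations,
        "per_line_mu_diploid": per_line,
        "rates": {k: _estimate_json(v) for k, v in headline.items()},
        "ts_tv": {"ratio": ratio, "ts": ts, "tv": tv},
        "ins_del_bias": {
            "chi2": ins_del.statistic, "p": ins_del.p_value,
            "observed": [ins, dele],
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "rate_table.tsv", sep="\t")
        with open(out / "counts_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary
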