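"""End-to-end orchestration: simulate (or load) -> descriptives -> structure
learning -> effect decomposition, with on-disk artifacts and full provenance.

A run is reproducible from its config and root seed alone; all randomness
flows from the root seed through named substreams, and stage boundaries are
logged with row counts (no silent row drops anywhere).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .descriptives import correlation_matrix, group_summary, pairwise_group_tests
from .effects import EffectDecomposition, decompose
from .errors import ConfigError
from .schema import apply_log_transforms, read_cohort, write_cohort, Cohort
from .simulate import GeneratorConfig, generate_cohort, learning_nodes
from .structure import ConstraintSet, Pdag, default_constraints, learn_pdag, load_constraints

log = logging.getLogger("aircausal")

SUMMARY_VARIABLES = (
    "age", "sex", "bmi", "lung_size", "pack_years", "fev1_fvc", "fev1_pct_pred", "scanner",
)
CT_VARIABLES = ("wt", "tac", "tac_p")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``generator`` (synthetic mode) or ``cohort_path`` (external
    cohort CSV) must be supplied.
    """

    generator: GeneratorConfig | None = None
    cohort_path: str | None = None
    alpha: float = 0.05
    outcomes: tuple = ("log_tac", "log_tac_p")
    constraints_path: str | None = None
    out_dir: str = "aircausal_run"
    seed: int = 0

    def __post_init__(self):
        if (self.generator is None) == (self.cohort_path is None):
            raise ConfigError("supply exactly one of generator config or cohort path")
        bad = [o for o in self.outcomes if o not in ("log_tac", "log_tac_p")]
        if bad:
            raise ConfigError(f"unknown outcomes {bad}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig(**gen)
        if "outcomes" in raw:
            raw["outcomes"] = tuple(raw["outcomes"])
        try:
            return cls(generator=gen, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict() if self.generator else None,
            "cohort_path": self.cohort_path,
            "alpha": self.alpha,
            "outcomes": list(self.outcomes),
            "constraints_path": self.constraints_path,
            "out_dir": str(self.out_dir),
            "seed": self.seed,
        }


@dataclass
class RunReport:
    cohort: Cohort
    summaries: dict
    tests: dict
    correlations: object
    pdags: dict[str, Pdag]
    decompositions: dict[str, EffectDecomposition]
    provenance: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order. Same config => identical report."""
    if config.generator is not None:
        log.info("stage simulate: n=%d seed=%d", config.generator.n, config.generator.seed)
        cohort = generate_cohort(config.generator)
    else:
        log.info("stage load: %s", config.cohort_path)
        cohort = read_cohort(config.cohort_path)
    log.info("cohort loaded: %d rows", cohort.n)

    cohort = apply_log_transforms(cohort)

    summaries = {
        "demographics": group_summary(cohort, SUMMARY_VARIABLES),
        "ct_outcomes": group_summary(cohort, CT_VARIABLES),
    }
    tests = {v: pairwise_group_tests(cohort, v) for v in ("age", "pack_years", *CT_VARIABLES)}
    correlations = correlation_matrix(cohort)
    log.info("stage descriptives done: %d variables correlated", len(correlations.variables))

    pdags, decomps = {}, {}
    for outcome in config.outcomes:
        constraints = (
            load_constraints(config.constraints_path)
            if config.constraints_path
            else default_constraints(outcome)
        )
        nodes = learning_nodes(outcome)
        pdag = learn_pdag(cohort.data, alpha=config.alpha, constraints=constraints, nodes=nodes)
        log.info(
            "stage learn (%s): %d directed, %d undirected edges",
            outcome, len(pdag.directed), len(pdag.undirected),
        )
        pdags[outcome] = pdag
        decomps[outcome] = decompose(pdag, cohort, outcome=outcome)
        log.info("stage effects (%s): n=%d", outcome, cohort.n)

    cfg_dict = config.to_dict()
    provenance = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "n": cohort.n,
    }
    return RunReport(cohort, summaries, tests, correlations, pdags, decomps, provenance)


def render_report(report: RunReport, out_dir) -> list[Path]:
    """Write CSV tables, DOT/JSON graphs, effect JSONs and a summary document."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(path: Path, text: str) -> None:
        path.write_text(text)
        written.append(path)

    write_cohort(report.cohort, out / "cohort.csv")
    written.append(out / "cohort.csv")
    report.summaries["demographics"].to_csv(out / "table_demographics.csv")
    report.summaries["ct_outcomes"].to_csv(out / "table_ct_outcomes.csv")
    written += [out / "table_demographics.csv", out / "table_ct_outcomes.csv"]
    for var, frame in report.tests.items():
        frame.to_csv(out / f"ttests_{var}.csv", index=False)
        written.append(out / f"ttests_{var}.csv")
    report.correlations.r.to_csv(out / "correlations.csv")
    written.append(out / "correlations.csv")

    lines = ["# aircausal run report", ""]
    for outcome, pdag in report.pdags.items():
        tag = outcome.replace("log_", "")
        save(out / f"dag_{tag}.dot", pdag.to_dot(name=tag))
        save(out / f"dag_{tag}.json", pdag.to_json())
        dec = report.decompositions[outcome]
        save(out / f"effects_{tag}.json", json.dumps(dec.to_dict(), indent=2, sort_keys=True))
        dec.percent_declines().to_csv(out / f"percent_declines_{tag}.csv", index=False)
        written.append(out / f"percent_declines_{tag}.csv")
        lines.append(f"## {outcome}")
        lines.append("")
        lines.append(dec.percent_declines().to_string(index=False))
        lines.append("")
        for grp, path in dec.dominant_pathway().items():
            other = "direct" if path == "indirect" else "indirect"
            lines.append(
                f"- {grp} COPD: the {path} pathway dominates the {other} pathway "
                f"({dec.percent_declines().set_index('group').loc[grp, f'{path}_decline_pct']:.2f}% "
                f"vs {dec.percent_declines().set_index('group').loc[grp, f'{other}_decline_pct']:.2f}% decline)"
            )
        lines.append("")
    save(out / "provenance.json", json.dumps(report.provenance, indent=2, sort_keys=True))
    save(out / "report.md", "\n".join(lines))
    return written
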