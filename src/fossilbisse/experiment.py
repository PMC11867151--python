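"""Factorial study orchestration: scenarios x fossil rates x replicates.

The full design matches the study: 4 scenarios x 4 fossil-sampling rates
(including psi = 0, extant-only) x 100 replicates = 1600 trees, each
carrying the focal trait and three neutral traits = 6400 tree-and-trait
datasets. A scale factor shrinks replicate counts and MCMC length
proportionally for desk runs; seeds are split per replicate with
counter-based spawn keys so any replicate can be regenerated alone.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .infer.diagnostics import convergence_report
from .infer.mcmc import MCMCSettings, PosteriorTrace, run_mcmc
from .infer.priors import PriorSpec, default_priors
from .io import read_dataset, serialize_dataset
from .params import NEUTRAL_TRAIT_SPECS, SCENARIOS, BisseParameters, NeutralTraitSpec
from .replicate import ReplicateDataset, generate_replicate
from .sim import FOCAL_TRAIT
from .summarize import AnalysisSetSummary, summarize_analysis_set

__all__ = [
    "StudyDesign",
    "RunManifest",
    "scenario_parameters",
    "run_study",
    "prior_calibration",
]


def scenario_parameters(scenario_id: str, psi: float = 0.0) -> BisseParameters:
    """The true rate vector of a study scenario (S1-S4)."""
    if scenario_id not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario_id!r}; expected one of {list(SCENARIOS)}")
    return SCENARIOS[scenario_id].parameters(psi=psi)


@dataclass(frozen=True)
class StudyDesign:
    scenarios: tuple[str, ...] = ("S1", "S2", "S3", "S4")
    psis: tuple[float, ...] = (0.0, 0.01, 0.05, 0.1)
    replicates: int = 100
    n_extant_stop: int = 100
    neutral_qs: tuple[float, ...] = (0.01, 0.1, 1.0)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    min_state_freq: float = 0.10

    @property
    def tree_count(self) -> int:
        return len(self.scenarios) * len(self.psis) * self.replicates

    @property
    def dataset_count(self) -> int:
        # one focal trait set plus one per neutral trait, on every tree
        return self.tree_count * (1 + len(self.neutral_qs))

    @property
    def neutral_specs(self) -> list[NeutralTraitSpec]:
        return [s for s in NEUTRAL_TRAIT_SPECS if s.q in self.neutral_qs] + [
            NeutralTraitSpec(q) for q in self.neutral_qs
            if q not in {s.q for s in NEUTRAL_TRAIT_SPECS}
        ]

    def scaled(self, scale: float) -> "StudyDesign":
        """Shrink replicate count, tip target and chain length by ``scale``."""
        if scale <= 0 or scale > 1:
            raise ValueError("scale must be in (0, 1]")
        if scale == 1.0:
            return self
        mcmc = replace(
            self.mcmc,
            iterations=max(500, int(self.mcmc.iterations * scale)),
            target_samples=min(self.mcmc.target_samples,
                               max(100, int(self.mcmc.target_samples * scale * 10))),
        )
        return replace(
            self,
            replicates=max(1, round(self.replicates * scale)),
            n_extant_stop=max(10, round(self.n_extant_stop * scale)),
            mcmc=mcmc,
        )


@dataclass
class RunManifest:
    master_seed: int
    design: dict
    scale: float
    version: str = __version__
    replicates: list[dict] = field(default_factory=list)
    analysis_sets: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def save(self, path: Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def entry(self, scenario: str, psi: float, rep: int) -> dict | None:
        for e in self.replicates:
            if e["scenario"] == scenario and e["psi"] == psi and e["rep"] == rep:
                return e
        return None


def replicate_seed(master_seed: int, scenario: str, psi: float, rep: int,
                   design: StudyDesign) -> int:
    """Deterministic per-replicate seed from the master seed (counter-based)."""
    ci = design.scenarios.index(scenario) * len(design.psis) + list(design.psis).index(psi)
    ss = np.random.SeedSequence(master_seed, spawn_key=(ci, rep))
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)


def _design_dict(design: StudyDesign) -> dict:
    d = {
        "scenarios": list(design.scenarios),
        "psis": list(design.psis),
        "replicates": design.replicates,
        "n_extant_stop": design.n_extant_stop,
        "neutral_qs": list(design.neutral_qs),
        "min_state_freq": design.min_state_freq,
        "mcmc": design.mcmc.__dict__ | {},
        "stopping_rule": "present set at the speciation event creating the n-th extant lineage",
    }
    return d


def simulate_replicate(design: StudyDesign, scenario: str, psi: float,
                       seed: int) -> ReplicateDataset:
    rng = np.random.default_rng(seed)
    return generate_replicate(
        SCENARIOS[scenario], psi, design.neutral_specs, design.n_extant_stop,
        rng, min_freq=design.min_state_freq,
    )


def run_study(
    design: StudyDesign,
    outdir: Path,
    master_seed: int = 0,
    scale: float = 1.0,
    stages: tuple[str, ...] = ("simulate", "infer", "summarize"),
    priors: PriorSpec | None = None,
    conditioning: str = "survival",
    progress=None,
) -> RunManifest:
    """Run (or resume) the factorial study into ``outdir``.

    Stage failures are recorded per replicate; the study continues and the
    manifest carries a failure table. Completed replicates found in an
    existing manifest are skipped.
    """
    design = design.scaled(scale)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
    else:
        manifest = RunManifest(master_seed=master_seed, design=_design_dict(design), scale=scale)
    priors = priors or default_priors()

    traces_by_set: dict[str, list[PosteriorTrace]] = {}

    for scenario in design.scenarios:
        for psi in design.psis:
            for rep in range(design.replicates):
                seed = replicate_seed(master_seed, scenario, psi, rep, design)
                rep_dir = outdir / f"{scenario}_psi{psi:g}" / f"rep{rep:03d}"
                entry = manifest.entry(scenario, psi, rep)
                if entry is None:
                    entry = {
                        "scenario": scenario, "psi": psi, "rep": rep, "seed": seed,
                        "dir": str(rep_dir.relative_to(outdir)), "status": "pending",
                        "files": [], "analyses": {},
                    }
                    manifest.replicates.append(entry)
                try:
                    dataset = _stage_simulate(design, scenario, psi, seed, rep_dir, entry)
                    if "infer" in stages:
                        _stage_infer(design, dataset, psi, seed, rep_dir, entry,
                                     priors, conditioning, traces_by_set, manifest)
                    entry["status"] = "done"
                except Exception as exc:  # noqa: BLE001 - per-replicate failure table
                    entry["status"] = f"failed: {exc}"
                if progress is not None:
                    progress(entry)
    if "summarize" in stages and "infer" in stages:
        _stage_summarize(design, traces_by_set, outdir, manifest)
    manifest.save(manifest_path)
    return manifest


def _stage_simulate(design, scenario, psi, seed, rep_dir, entry) -> ReplicateDataset:
    if entry["status"] == "done" and (Path(rep_dir) / "meta.yaml").exists():
        return read_dataset(rep_dir)
    dataset = simulate_replicate(design, scenario, psi, seed)
    serialize_dataset(dataset, rep_dir, seed=seed)
    entry["rejections"] = dataset.rejections
    entry["files"] = sorted(p.name for p in Path(rep_dir).iterdir())
    return dataset


def _analysis_sets_for(design, psi: float) -> list[tuple[str, str]]:
    """(view, trait) pairs analysed for one design cell."""
    traits = [FOCAL_TRAIT] + [s.label for s in design.neutral_specs]
    pairs = [("extant", t) for t in traits]
    if psi > 0:
        pairs += [("fbd", t) for t in traits]
    return pairs


def _stage_infer(design, dataset, psi, seed, rep_dir, entry, priors,
                 conditioning, traces_by_set, manifest) -> None:
    for view, trait in _analysis_sets_for(design, psi):
        set_id = f"{dataset.scenario_id}_psi{psi:g}_{view}_{trait}"
        trace_path = Path(rep_dir) / f"trace_{view}_{trait}.csv"
        tree = dataset.extant if view == "extant" else dataset.fbd
        model = "bisse" if view == "extant" else "bisse_fbd"
        if trace_path.exists() and set_id in entry["analyses"]:
            trace = PosteriorTrace.from_csv(trace_path)
        else:
            analysis_seed = (seed + zlib.crc32(f"{view}|{trait}".encode())) % (2**31)
            trace = run_mcmc(
                tree, model, priors=priors, settings=design.mcmc, trait=trait,
                seed=analysis_seed, conditioning=conditioning,
            )
            trace.to_csv(trace_path)
            report = convergence_report(trace, path=Path(rep_dir) / f"ess_{view}_{trait}.json")
            entry["analyses"][set_id] = {
                "trace": trace_path.name,
                "ess_flagged": report["flagged"],
            }
            if report["flagged"]:
                manifest.warnings.append(
                    f"{set_id} rep {entry['rep']}: ESS < {report['threshold']} "
                    f"for {report['flagged']}"
                )
        traces_by_set.setdefault(set_id, []).append(trace)


def prior_calibration(
    n_runs: int = 50,
    n_tips: int = 30,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    master_seed: int = 0,
    conditioning: str = "survival",
    sim_cap: int = 500,
):
    """Simulation-based calibration of the extant-view BiSSE analysis.

    True parameters are drawn from the priors, a small extant tree is
    simulated (root state drawn with probability pi0), and the same
    priors are used for inference; if the model and sampler behave, each
    parameter's 95% interval should cover its truth ~95% of the time.
    Parameter draws whose process cannot reach the tip target within
    ``sim_cap`` attempts are redrawn (an approximation to exact survival
    conditioning for parameter regions of negligible survival
    probability). Returns (table, coverage-by-parameter dict).
    """
    import pandas as pd

    from .fossilize import prune_to_extant
    from .sim import RejectionBudgetExceeded, simulate_complete_tree
    from .summarize import summarize_trace

    priors = priors or default_priors()
    settings = settings or MCMCSettings(iterations=10_000)
    names = ["lambda0", "lambda1", "mu0", "mu1", "q01", "q10", "pi0"]
    rows = []
    for i in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(i,)))
        while True:
            truth = {n: priors[n].sample(rng) for n in names}
            params = BisseParameters(
                truth["lambda0"], truth["lambda1"], truth["mu0"], truth["mu1"],
                truth["q01"], truth["q10"], pi0=truth["pi0"],
            )
            root_state = 0 if rng.random() < truth["pi0"] else 1
            try:
                tree = simulate_complete_tree(
                    params, n_tips, rng, max_rejections=sim_cap, root_state=root_state
                )
                break
            except RejectionBudgetExceeded:
                continue
        extant = prune_to_extant(tree)
        trace = run_mcmc(
            extant, "bisse", priors=priors, settings=settings,
            seed=int(rng.integers(2**31)), conditioning=conditioning,
        )
        s = summarize_trace(trace).set_index("parameter")
        for n in names:
            rows.append(
                {
                    "run": i,
                    "parameter": n,
                    "truth": truth[n],
                    "mean": s.loc[n, "mean"],
                    "lower95": s.loc[n, "lower95"],
                    "upper95": s.loc[n, "upper95"],
                    "covered": bool(s.loc[n, "lower95"] <= truth[n] <= s.loc[n, "upper95"]),
                }
            )
    table = pd.DataFrame(rows)
    coverage = table.groupby("parameter")["covered"].mean().to_dict()
    return table, coverage


def _stage_summarize(design, traces_by_set, outdir, manifest) -> None:
    summary_dir = outdir / "summaries"
    summary_dir.mkdir(exist_ok=True)
    rollups = []
    for set_id, traces in traces_by_set.items():
        scenario = set_id.split("_")[0]
        trait = set_id.split("_", 3)[3]
        truth = scenario_parameters(scenario).as_dict() if trait == FOCAL_TRAIT else {}
        summary = summarize_analysis_set(
            traces, truth, inequality=("lambda1", "lambda0")
        )
        summary.table.to_csv(summary_dir / f"{set_id}.csv", index=False)
        entry = {"set": set_id, "n": len(traces),
                 "p_lambda1_gt_lambda0": summary.inequality_probs}
        if truth:
            entry["rollup"] = summary.rollup().to_dict("records")
        rollups.append(entry)
        manifest.analysis_sets[set_id] = entry
    with open(summary_dir / "rollup.json", "w") as fh:
        json.dump(rollups, fh, indent=2, sort_keys=True)
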