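"""End-to-end orchestration: diversity → differentiation → marker power →
parentage → classification → Nb → mating models → assortative test.

`run_pipeline` consumes either real input files (GenePop + phenotype TSV)
or a simulation configuration, executes the stages in study order, and
writes TSV report files plus a JSON manifest capturing configuration,
seeds and input hashes so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import breeders, mating, parentage, popgen
from .genotype_data import (
    GenotypeTable,
    Individual,
    Origin,
    Tactic,
    attach_phenotypes,
    read_genepop,
    read_phenotypes,
)
from .simulate import SimulationConfig, simulate_mesocosm

__all__ = ["RunConfig", "run_pipeline", "summarize_contributions"]

log = logging.getLogger("mesoped.pipeline")


@dataclass
class RunConfig:
    genotypes: str | None = None  # GenePop path (real-input mode)
    phenotypes: str | None = None  # phenotype TSV path (real-input mode)
    simulation: SimulationConfig | None = None  # simulate mode
    flag_loci: Sequence[str] = ()  # loci to flag as null-bearing
    mc: popgen.McTestConfig = field(
        default_factory=lambda: popgen.McTestConfig(1_000, 100, 500)
    )
    covariate_mode: str = "length"
    fdr_method: str = "bh"
    fdr_alpha: float = 0.05
    error_rate: float = 0.02
    outdir: str = "mesoped_out"
    seed: int = 0
    run_hw_tests: bool = False  # chain tests are opt-in (slow on big tables)

    def __post_init__(self) -> None:
        real = self.genotypes is not None
        if real == (self.simulation is not None):
            raise ValueError("exactly one of real-input and simulate modes")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must lie in (0, 1)")


def _load(cfg: RunConfig):
    if cfg.simulation is not None:
        sim = simulate_mesocosm(cfg.simulation)
        combined = GenotypeTable(
            sim.adults.panel,
            sim.adults.individuals + sim.offspring.individuals,
            np.concatenate([sim.adults.calls, sim.offspring.calls]),
        )
        return combined, sim.registry, sim
    table = read_genepop(cfg.genotypes)
    if cfg.phenotypes:
        table = attach_phenotypes(table, read_phenotypes(cfg.phenotypes))
    registry = {ind.id: ind for ind in table.individuals}
    return table, registry, None


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages and write the report bundle to ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    reports: dict[str, pd.DataFrame] = {}

    def stage(name, fn):
        start = time.time()
        try:
            out = fn()
        except Exception as exc:  # keep partial outputs, name the stage
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        log.info("stage %s done in %.1fs", name, time.time() - start)
        return out

    table, registry, sim = stage("load", lambda: _load(cfg))
    for name in cfg.flag_loci:
        table.flag_locus(name)

    # -- diversity (per group + total) -----------------------------------
    def diversity():
        frames = []
        groups = [Origin.SOUTH, Origin.WEST, Origin.OFFSPRING, None]
        sizes = [
            table.subset(origin=g).n_individuals if g else table.n_individuals
            for g in groups
        ]
        g_copies = 2 * min(s for s in sizes[:3] if s > 0)
        for g, label in zip(groups, ["south", "west", "offspring", "total"]):
            try:
                df = popgen.locus_summary_table(table, g, rarefaction_g=g_copies)
            except ValueError:
                continue
            df.insert(0, "group", label)
            frames.append(df.reset_index())
        return pd.concat(frames, ignore_index=True)

    reports["diversity"] = stage("diversity", diversity)

    # -- differentiation --------------------------------------------------
    reports["pairwise_fst"] = stage(
        "differentiation",
        lambda: popgen.pairwise_fst_table(
            table, g_test=cfg.run_hw_tests, cfg=cfg.mc
        ),
    )

    if cfg.run_hw_tests:
        def hw():
            rows = []
            for g, label in [(Origin.SOUTH, "south"), (Origin.WEST, "west"),
                             (Origin.OFFSPRING, "offspring")]:
                if table.subset(origin=g).n_individuals == 0:
                    continue
                for loc in table.panel:
                    res = popgen.hw_exact_test(table, g, loc.name, cfg.mc)
                    rows.append({"group": label, "locus": loc.name,
                                 "p": res.p_value, "mc_se": res.mc_se})
            df = pd.DataFrame(rows)
            adj = popgen.fdr_adjust(df["p"], cfg.fdr_method, cfg.fdr_alpha)
            return pd.concat([df, adj[["p_adjusted", "reject"]]], axis=1)

        reports["hw_tests"] = stage("hw_tests", hw)

    # -- marker power ------------------------------------------------------
    freqs = popgen.allele_freqs(table, None)
    reports["marker_power"] = stage(
        "marker_power",
        lambda: parentage.marker_power_table(
            {k: v for k, v in freqs.items() if v}
        ).reset_index(),
    )

    # -- parentage ---------------------------------------------------------
    def do_parentage():
        offspring = table.subset(origin=Origin.OFFSPRING)
        adults = table.subset(origin=[Origin.SOUTH, Origin.WEST])
        mothers, fathers = parentage.split_candidates(adults)
        return parentage.assign_parentage(
            offspring, mothers, fathers, freqs, error_rate=cfg.error_rate
        )

    assignments = stage("parentage", do_parentage)
    reports["pedigree"] = pd.DataFrame(
        [
            {
                "offspring_id": a.offspring_id,
                "mother_id": a.mother_id,
                "father_id": a.father_id,
                "lod": a.lod,
                "mismatches": a.mismatches,
                "origin_class": a.origin_class,
                "status": a.status,
            }
            for a in assignments
        ]
    )

    # -- contributions / Nb / models --------------------------------------
    reports["contributions"] = stage(
        "contributions", lambda: summarize_contributions(assignments, registry)
    )
    reports["nb"] = stage("nb", lambda: breeders.nb_report(assignments, registry))

    def models():
        pairs = mating.build_pair_table(assignments, registry, cfg.covariate_mode)
        out = {}
        try:
            out["success"] = mating.MatingSuccessModel(pairs).fit().summary()
        except ValueError as exc:
            out["success"] = pd.DataFrame({"error": [str(exc)]})
        try:
            out["count"] = mating.OffspringCountModel(pairs).fit().summary()
        except ValueError as exc:
            out["count"] = pd.DataFrame({"error": [str(exc)]})
        return out

    fits = stage("mating_models", models)
    reports["model_success"] = fits["success"]
    reports["model_count"] = fits["count"]

    def assort():
        res = mating.assortative_test(assignments, registry)
        tab = res.table.reset_index(names="male_origin")
        tab["chi2"] = res.chi2
        tab["p_value"] = res.p_value
        return tab

    reports["assortative"] = stage("assortative", assort)

    # -- write bundle ------------------------------------------------------
    for name, df in reports.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                  lineterminator="\n", float_format="%.6g")
    manifest = {
        "seed": cfg.seed,
        "mode": "simulate" if cfg.simulation else "real",
        "simulation_seed": sim.seed if sim else None,
        "mc": cfg.mc.__dict__,
        "covariate_mode": cfg.covariate_mode,
        "fdr": {"method": cfg.fdr_method, "alpha": cfg.fdr_alpha},
        "error_rate": cfg.error_rate,
        "flag_loci": list(cfg.flag_loci),
        "reports": {
            name: hashlib.sha256(
                (outdir / f"{name}.tsv").read_bytes()
            ).hexdigest()
            for name in reports
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    if sim is not None:
        sim.write(outdir / "simulated_inputs")
    return reports


def summarize_contributions(
    assignments: Sequence[parentage.PedigreeAssignment],
    registry: Mapping[str, Individual],
) -> pd.DataFrame:
    """Contribution summary per origin x tactic: contributing parents,
    offspring by origin class, family counts, largest family, mean ± SD
    family size."""
    strata = [
        (o, t)
        for o in (Origin.SOUTH, Origin.WEST)
        for t in (Tactic.NESTING_MALE, Tactic.FEMALE, Tactic.SNEAKER_MALE)
    ]
    classes = ["south", "hybrid", "west"]
    rows = []
    resolved = [a for a in assignments if a.status == "assigned"]
    for origin, tactic in strata:
        members = {
            i.id for i in registry.values()
            if i.origin is origin and i.tactic is tactic
        }
        if not members:
            continue
        fam: dict[tuple[str, str], int] = {}
        per_parent: dict[str, int] = {}
        by_class = {c: 0 for c in classes}
        for a in resolved:
            pid = a.father_id if tactic is not Tactic.FEMALE else a.mother_id
            if pid not in members:
                continue
            per_parent[pid] = per_parent.get(pid, 0) + 1
            fam_key = (a.father_id, a.mother_id)
            fam[fam_key] = fam.get(fam_key, 0) + 1
            by_class[a.origin_class] += 1
        sizes = np.array(list(fam.values())) if fam else np.array([0])
        rows.append(
            {
                "origin": origin.value,
                "tactic": tactic.value,
                "n_present": len(members),
                "n_contributing": len(per_parent),
                "pct_contributing": 100.0 * len(per_parent) / len(members),
                "offspring_total": sum(per_parent.values()),
                "offspring_south": by_class["south"],
                "offspring_hybrid": by_class["hybrid"],
                "offspring_west": by_class["west"],
                "n_families": len(fam) if per_parent else 0,
                "largest_family": int(sizes.max()) if per_parent else 0,
                "family_size_mean": float(sizes.mean()) if per_parent else 0.0,
                "family_size_sd": float(sizes.std()) if per_parent else 0.0,
            }
        )
    return pd.DataFrame(rows)
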