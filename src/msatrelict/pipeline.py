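"""End-to-end orchestration: synthetic study generation and the full
analysis workflow (ploidy -> diversity -> pseudo-diploidisation -> ABC).

The synthetic study generator emulates the North-African alder survey
design: three regional gene pools (Morocco tetraploid, Tunisia+Algeria
diploid, Scotland diploid) simulated under one of the seven divergence
scenarios, then partitioned into the 19+1 sampling-site populations with
the survey's sample sizes and ploidies.  Sub-structure *within* a region is
not modelled — population labels inside a region partition an exchangeable
regional sample.

The analysis runner mirrors the study workflow: infer ploidy, estimate
per-population diversity (Hs, rarefied rHs) and compare countries by
Kruskal-Wallis, pseudo-diploidise the tetraploid representative, then run
the ABC machinery (reference table, scenario choice, parameter estimation,
and optionally the confusion / estimation-quality assessments) on three
representative populations.  All stages are seeded; a fixed seed
reproduces every number.  Reports are plain CSV tables plus a JSON
metadata sidecar.
"""

from __future__ import annotations

import json
import traceback
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc as abcmod
from . import coalsim, diversity, polyploid, sumstats
from .datasets import SURVEY_REPRESENTATIVES, alder_survey_table
from .genodata import Genotype, Individual, Locus, MsatDataset, Population

__all__ = [
    "PopulationDesign",
    "StudyConfig",
    "generate_synthetic_study",
    "run_full_analysis",
]

#: region -> coalescent deme index (N1 Morocco, N2 Tunisia/Algeria, N3 ref)
_REGION_DEME = {"morocco": 0, "tunisia": 1, "algeria": 1, "scotland": 2}


@dataclass
class PopulationDesign:
    code: str
    country: str
    n: int
    ploidy: int
    altitude: float | None = None

    @property
    def deme(self) -> int:
        try:
            return _REGION_DEME[self.country.lower()]
        except KeyError:
            raise ValueError(
                f"population {self.code}: country {self.country!r} maps to no "
                "regional gene pool"
            ) from None


def _default_design() -> list[PopulationDesign]:
    t = alder_survey_table()
    return [
        PopulationDesign(
            code=r.code, country=r.country, n=int(r.n), ploidy=int(r.ploidy),
            altitude=float(r.altitude),
        )
        for r in t.itertuples()
    ]


@dataclass
class StudyConfig:
    """Everything needed to generate and analyse one synthetic study."""

    seed: int
    populations: list[PopulationDesign] = field(default_factory=_default_design)
    true_scenario: int = 5
    true_params: dict[str, float] | None = None
    n_loci: int = 11
    motif_length: int = 2
    origin_bp: int = 200
    representatives: tuple[str, str, str] = SURVEY_REPRESENTATIVES
    rarefaction_g: int = 12
    rarefaction_replicates: int = 200
    abc_n_per_scenario: int = 2000
    abc_n_closest: int = 200
    # retained fraction for local-linear estimation; at the default table
    # size this keeps 200 rows, comfortably above the regression dimension
    abc_n_keep: float = 0.1
    power_n_pseudo: int = 0  # 0 disables the confusion / quality stages
    generation_time: float = 10.0

    def __post_init__(self) -> None:
        self.populations = [
            p if isinstance(p, PopulationDesign) else PopulationDesign(**p)
            for p in self.populations
        ]
        if self.seed is None:
            raise ValueError("a seed is mandatory for every stochastic stage")
        for p in self.populations:
            if p.ploidy not in (2, 4):
                raise ValueError(f"{p.code}: ploidy must be 2 or 4")
            if p.ploidy == 4 and p.deme != 0:
                raise ValueError(
                    f"{p.code}: tetraploid populations belong to the Moroccan "
                    "gene pool in this design"
                )

    # -- lossless file round-trip ---------------------------------------

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["representatives"] = list(self.representatives)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["representatives"] = tuple(data["representatives"])
        return cls(**data)


def _draw_true_params(
    config: StudyConfig, rng: np.random.Generator
) -> tuple[coalsim.ParamVector, coalsim.MutationModel]:
    scenario = coalsim.DemographicScenario.from_id(config.true_scenario)
    pv, mm = coalsim.sample_priors(scenario, rng, n_loci=config.n_loci)
    if config.true_params:
        pv = coalsim.ParamVector(
            **{
                nm: float(config.true_params.get(nm, getattr(pv, nm)))
                for nm in abcmod.PARAM_COLS
            }
        )
    return pv, mm


def generate_synthetic_study(
    config: StudyConfig,
) -> tuple[MsatDataset, dict]:
    """Simulate the full 20-population synthetic analogue of the survey.

    Returns the dataset and a truth sidecar (scenario, parameters, seeds)
    for later power evaluation.  Byte-identical for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    scenario = coalsim.DemographicScenario.from_id(config.true_scenario)
    pv, mm = _draw_true_params(config, rng)

    demes: dict[int, list[PopulationDesign]] = {0: [], 1: [], 2: []}
    for p in config.populations:
        demes[p.deme].append(p)
    copies_per_deme = [
        sum(p.n * p.ploidy for p in demes[d]) for d in range(3)
    ]
    # the coalescent operates on gene copies; feed copy counts as "diploid
    # individuals" of 2 copies each (counts are even by construction)
    cfg = coalsim.SampleConfig(
        n_individuals=tuple(c // 2 for c in copies_per_deme),
        ploidies=(2, 2, 2),
        n_loci=config.n_loci,
        motif_length=config.motif_length,
        origin_bp=config.origin_bp,
    )
    matrix = coalsim.simulate_allele_matrix(
        scenario, pv, mm, cfg, rng=int(rng.integers(0, 2**31))
    )
    loci = [Locus(f"L{j + 1:02d}", config.motif_length) for j in range(config.n_loci)]
    populations = {
        p.code: Population(code=p.code, country=p.country, altitude=p.altitude)
        for p in config.populations
    }
    individuals: list[Individual] = []
    offsets = {d: int(np.sum([0] + copies_per_deme[:d])) for d in range(3)}
    for d in range(3):
        row = offsets[d]
        for p in demes[d]:
            for i in range(p.n):
                block = matrix[row : row + p.ploidy]
                row += p.ploidy
                genotypes = {}
                for j, locus in enumerate(loci):
                    alleles = block[:, j]
                    if p.ploidy == 4:
                        alleles = np.unique(alleles)  # ambiguous dosage
                    genotypes[locus.name] = Genotype(alleles.tolist())
                individuals.append(
                    Individual(
                        id=f"{p.code}_{i + 1:03d}",
                        population=p.code,
                        genotypes=genotypes,
                        ploidy=p.ploidy,
                    )
                )
    dataset = MsatDataset(loci=loci, populations=populations, individuals=individuals)
    truth = {
        "scenario": config.true_scenario,
        "params": {
            nm: getattr(pv, nm)
            for nm in scenario.param_names
        },
        "mu_mean": float(np.mean(mm.mu)),
        "p_mean": float(np.mean(mm.p)),
        "seed": config.seed,
    }
    return dataset, truth


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------


def _diversity_table(
    dataset: MsatDataset, report: polyploid.PloidyReport, config: StudyConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for code, pop in dataset.populations.items():
        inds = dataset.population_individuals(code)
        hs = diversity.gene_diversity_hs(dataset, code)
        rhs, se = diversity.rarefied_diversity(
            dataset, code, g=config.rarefaction_g,
            replicates=config.rarefaction_replicates,
            rng=rng, return_se=True,
        )
        nal = report.nal_counts[code]
        rows.append(
            {
                "code": code,
                "country": pop.country,
                "n": len(inds),
                "nal1a": nal[0], "nal2a": nal[1], "nal3a": nal[2], "nal4a": nal[3],
                "ploidy": report.population_ploidy[code],
                "hs": round(hs, 4),
                "rhs": round(rhs, 4),
                "rhs_se": round(se, 4),
            }
        )
    return pd.DataFrame(rows)


def _merge_for_abc(
    dataset: MsatDataset, config: StudyConfig, rng: np.random.Generator,
    report: polyploid.PloidyReport,
) -> MsatDataset:
    """Three representative populations, tetraploids pseudo-diploidised."""
    codes = config.representatives
    loci = dataset.loci
    populations = {}
    individuals = []
    for code in codes:
        if report.population_ploidy[code] == 4:
            freqs = polyploid.estimate_freqs_mixed(dataset, code)
            psd = polyploid.sample_pseudo_diploids(
                freqs, n=30, rng=rng, population_code=code,
                country=dataset.populations[code].country,
            )
            populations[code] = psd.populations[code]
            individuals.extend(psd.individuals)
        else:
            populations[code] = dataset.populations[code]
            kept = [
                i for i in dataset.population_individuals(code)
                if all(
                    not i.genotypes.get(l.name, Genotype()).is_missing
                    for l in loci
                )
            ]
            individuals.extend(kept)
    return MsatDataset(loci=list(loci), populations=populations,
                       individuals=individuals)


def run_full_analysis(
    dataset: MsatDataset,
    config: StudyConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the complete analysis and return the report bundle.

    The bundle holds five tables (diversity, country rank test, scenario
    posterior probabilities, parameter posterior summary, and — when
    ``power_n_pseudo`` > 0 — the confusion and estimation-quality tables)
    plus metadata with every seed.  Stage failures are recorded in a
    failure manifest without aborting later stages that do not depend on
    them.  With ``out_dir`` the tables are written as CSV files and the
    metadata as JSON.
    """
    rng = np.random.default_rng(config.seed + 1)
    bundle: dict = {"failures": {}}
    meta = {
        "seed": config.seed,
        "representatives": list(config.representatives),
        "abc_n_per_scenario": config.abc_n_per_scenario,
        "abc_n_closest": config.abc_n_closest,
        "abc_n_keep": config.abc_n_keep,
        "generation_time": config.generation_time,
    }

    report = polyploid.infer_ploidy(dataset)
    try:
        bundle["diversity"] = _diversity_table(dataset, report, config, rng)
        by_country: dict[str, list[float]] = {}
        for r in bundle["diversity"].itertuples():
            if sum(
                1 for q in bundle["diversity"].itertuples() if q.country == r.country
            ) >= 2:
                by_country.setdefault(r.country, []).append(r.rhs)
        kw = diversity.kruskal_wallis(by_country)
        bundle["country_test"] = pd.DataFrame(
            [{"statistic": "kruskal_h", "value": kw.h},
             {"statistic": "df", "value": kw.df},
             {"statistic": "pvalue", "value": kw.pvalue}]
        )
    except Exception as exc:  # pragma: no cover - defensive
        bundle["failures"]["diversity"] = _fail(exc)

    try:
        merged = _merge_for_abc(dataset, config, rng, report)
        observed = sumstats.summarize(merged, list(config.representatives))
        table = abcmod.build_reference_table(
            list(coalsim.SCENARIO_IDS),
            config.abc_n_per_scenario,
            coalsim.SampleConfig(
                n_individuals=tuple(
                    len(merged.population_individuals(c))
                    for c in config.representatives
                ),
                ploidies=(2, 2, 2),
                n_loci=config.n_loci,
                motif_length=config.motif_length,
                origin_bp=config.origin_bp,
            ),
            rng=np.random.default_rng(config.seed + 2),
        )
        choice = abcmod.model_choice(table, observed, n_closest=config.abc_n_closest)
        bundle["model_choice"] = pd.DataFrame(
            [
                {
                    "scenario": sid,
                    "posterior_p": choice.probabilities[sid],
                    "ci_low": choice.ci[sid][0],
                    "ci_high": choice.ci[sid][1],
                }
                for sid in choice.scenario_ids
            ]
        )
        meta["chosen_scenario"] = choice.chosen
        summary = abcmod.estimate_parameters(
            table, choice.chosen, observed, n_keep=config.abc_n_keep
        )
        rows = []
        for nm in summary.param_names:
            row = {
                "param": nm,
                "mode": summary.mode[nm],
                "q05": summary.q05[nm],
                "q95": summary.q95[nm],
            }
            if nm.startswith("t"):
                row["mode_years"] = diversity.generations_to_years(
                    summary.mode[nm], config.generation_time
                )
                row["q05_years"] = diversity.generations_to_years(
                    summary.q05[nm], config.generation_time
                )
                row["q95_years"] = diversity.generations_to_years(
                    summary.q95[nm], config.generation_time
                )
            rows.append(row)
        bundle["parameters"] = pd.DataFrame(rows)
    except Exception as exc:
        bundle["failures"]["abc"] = _fail(exc)
        table = None

    if table is not None and config.power_n_pseudo > 0:
        try:
            sample_cfg = coalsim.SampleConfig(
                n_individuals=tuple(
                    len(merged.population_individuals(c))
                    for c in config.representatives
                ),
                ploidies=(2, 2, 2),
                n_loci=config.n_loci,
                motif_length=config.motif_length,
                origin_bp=config.origin_bp,
            )
            conf = abcmod.assess_confidence(
                table, sample_cfg, np.random.default_rng(config.seed + 3),
                n_pseudo=config.power_n_pseudo, n_closest=config.abc_n_closest,
            )
            bundle["confusion"] = pd.DataFrame(
                conf.matrix,
                index=[f"true_{s}" for s in conf.scenario_ids],
                columns=[f"assigned_{s}" for s in conf.scenario_ids],
            )
            quality = abcmod.assess_estimation(
                table, meta.get("chosen_scenario", config.true_scenario),
                sample_cfg, np.random.default_rng(config.seed + 4),
                n_pseudo=config.power_n_pseudo, n_keep=config.abc_n_keep,
            )
            bundle["quality"] = pd.DataFrame(
                [
                    {
                        "param": nm,
                        "relative_bias": quality.relative_bias[nm],
                        "relative_rmse": quality.relative_rmse[nm],
                        "factor2": quality.factor2[nm],
                    }
                    for nm in quality.param_names
                ]
            )
        except Exception as exc:
            bundle["failures"]["power"] = _fail(exc)

    bundle["metadata"] = meta
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out / f"{name}.csv", index=name == "confusion")
        with open(out / "metadata.json", "w") as fh:
            json.dump(
                {"metadata": meta, "failures": bundle["failures"]}, fh, indent=2
            )
    return bundle


def _fail(exc: Exception) -> dict:
    warnings.warn(f"analysis stage failed: {exc}")
    return {"error": str(exc), "traceback": traceback.format_exc()}
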