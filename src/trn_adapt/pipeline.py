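"""End-to-end study orchestration under a single YAML-able config.

``run_study`` chains the stages: (optionally) simulate inputs, apply the
basal iModulon transformation, compute TRN network statistics, call growth
from phenotyping plates, detect convergent mutations, and classify each
knockout strain into the four adaptation categories.  All randomness flows
from the single config seed; a rerun with the same config produces a
byte-identical JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from trn_adapt import imodulons as imod
from trn_adapt import mutations as mut
from trn_adapt import network as net
from trn_adapt import plates as plt
from trn_adapt import selection as sel
from trn_adapt import synthetic as syn
from trn_adapt.errors import (
    DegenerateStatisticError,
    InvalidSpecError,
    MissingInputError,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "basal", "network", "plates", "mutations", "classify")

_THRESHOLD_RANGES = {
    "defect": (0.0, 1.0),
    "match_r": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "lfc": (0.0, 20.0),
    "delta_activity": (0.0, 1e6),
    "min_lineages": (1, 100),
    "activity_fraction": (0.0, 1.0),
    "recovery": (0.0, 2.0),
    "frequency_floor": (0.0, 1.0),
}


@dataclass
class Thresholds:
    defect: float = 0.20
    match_r: float = 0.6
    alpha: float = 0.05
    lfc: float = 1.0
    delta_activity: float = 5.0
    min_lineages: int = 2
    activity_fraction: float = 0.10
    recovery: float = 0.95
    frequency_floor: float = 0.05


@dataclass
class StudyConfig:
    """Paths to inputs (or a simulation spec), thresholds, seed, output dir."""

    out_dir: str = "study_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    inputs: dict = field(default_factory=dict)
    simulate: syn.SyntheticStudySpec | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    convergence_partners: dict = field(default_factory=dict)  # ko -> extra gene list

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "StudyConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        thr_raw = raw.pop("thresholds", {})
        if isinstance(thr_raw, Thresholds):
            thresholds = thr_raw
        else:
            bad = set(thr_raw) - {f.name for f in dataclasses.fields(Thresholds)}
            if bad:
                raise InvalidSpecError(f"unknown threshold keys: {sorted(bad)}")
            thresholds = Thresholds(**thr_raw)
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(thresholds, name)
            if not lo <= v <= hi:
                raise InvalidSpecError(f"threshold {name}={v} outside [{lo}, {hi}]")
        sim_raw = raw.pop("simulate", None)
        sim = None
        if sim_raw is not None:
            if isinstance(sim_raw, syn.SyntheticStudySpec):
                sim = sim_raw
            else:
                sim_raw = dict(sim_raw)
                kos = [
                    syn.KnockoutSpec(**{**k, "convergent_genes": tuple(k.get("convergent_genes", ()))})
                    for k in sim_raw.pop("ko_specs", [])
                ]
                plate = syn.PlateSpec(**sim_raw.pop("plate_spec", {}))
                sim_raw["hub_tfs"] = tuple(sim_raw.get("hub_tfs", ()))
                sim = syn.SyntheticStudySpec(ko_specs=tuple(kos), plate_spec=plate, **sim_raw)
        cfg = cls(thresholds=thresholds, simulate=sim, **raw)
        cfg.stages = tuple(cfg.stages)
        bad_stages = set(cfg.stages) - set(ALL_STAGES)
        if bad_stages:
            raise InvalidSpecError(f"unknown stages: {sorted(bad_stages)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _require(inputs: dict, key: str, stage: str):
    if key not in inputs or inputs[key] is None:
        raise MissingInputError(f"stage {stage!r} requires input {key!r}")
    return inputs[key]


def _load_inputs(config: StudyConfig) -> dict:
    """Resolve configured paths into in-memory objects (lazy, best effort)."""
    loaded: dict[str, Any] = {}
    paths = config.inputs
    if "regulon" in paths:
        loaded["regulon"] = net.RegulonTable.from_tsv(paths["regulon"])
    if "expression" in paths:
        loaded["expression"] = imod.read_expression(paths["expression"], paths.get("samples"))
    if "m" in paths and "a" in paths:
        loaded["decomposition"] = imod.read_decomposition(
            paths["m"], paths["a"], paths.get("annotations")
        )
    if "mutations" in paths:
        loaded["mutations"] = mut.MutationTable.from_tsv(paths["mutations"])
    if "growth_impacts" in paths:
        loaded["growth_impacts"] = sel.GrowthImpactTable.from_csv(paths["growth_impacts"])
    if "growth_rates" in paths:
        loaded["growth_rates"] = pd.read_csv(paths["growth_rates"], index_col=0)
    plate_paths = paths.get("plates", {})
    if plate_paths:
        loaded["plates"] = {s: plt.PlateKinetics.from_csv(p) for s, p in plate_paths.items()}
    return loaded


def run_study(config: StudyConfig) -> dict:
    """Execute the configured stages and return the machine-readable report.

    Per-stage CSVs and ``report.json`` are written under ``config.out_dir``.
    The report maps stage name -> results; classification carries the
    four-way category per knockout.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    report: dict[str, Any] = {"seed": config.seed, "stages": list(config.stages)}

    if "simulate" in config.stages:
        if config.simulate is None:
            raise MissingInputError("stage 'simulate' requires a simulation spec")
        spec = dataclasses.replace(config.simulate, seed=config.simulate.seed or config.seed)
        study = syn.simulate_study(spec)
        sim_dir = out / "inputs"
        study.write(sim_dir)
        logger.info("stage=simulate out=%s", sim_dir)
        data = {
            "regulon": study.trn,
            "expression": study.expression,
            "decomposition": study.decomposition,
            "plates": study.plates,
            "mutations": study.mutations,
            "growth_impacts": study.growth_impacts,
            "growth_rates": study.growth_rates,
        }
        truth = study.ground_truth
        # path recorded relative to out_dir so reports stay byte-identical
        # across reruns in different locations
        report["simulate"] = {"inputs_dir": sim_dir.name}
    else:
        data = _load_inputs(config)
        truth = None

    basal = None
    decomposition = None
    if "basal" in config.stages:
        d: imod.Decomposition = _require(data, "decomposition", "basal")
        x: imod.ExpressionMatrix = _require(data, "expression", "basal")
        refs = x.reference_ids
        if not refs:
            raise MissingInputError("stage 'basal' requires reference samples")
        directions = {}
        ko_col = (x.samples["ko"] if "ko" in x.samples.columns
                  else pd.Series("", index=x.samples.index))
        for im in d.imodulons:
            reg = d.regulator_of(im)
            ko_ids = list(x.samples.index[ko_col == reg]) if reg else []
            ann_dir = None
            if "annotated_direction" in d.annotations.columns:
                v = d.annotations.loc[im, "annotated_direction"]
                ann_dir = int(v) if pd.notna(v) else None
            directions[im] = imod.assign_direction(
                d.A.loc[im], refs, ko_sample_ids=ko_ids or None,
                annotated_direction=ann_dir,
            )
        decomposition, basal = imod.basal_transform(d, directions, refs)
        basal.A_basal.to_csv(out / "basal_activity.csv")
        summary = pd.DataFrame({
            "direction": pd.Series(basal.directions),
            "offset": pd.Series(basal.offsets),
            "reference_max": basal.A_basal[refs].max(axis=1),
        })
        summary.rename_axis("imodulon").to_csv(out / "basal_summary.csv")
        logger.info("stage=basal n_imodulons=%d", len(directions))
        report["basal"] = {
            "directions": {k: int(v) for k, v in basal.directions.items()},
            "offsets": {k: float(v) for k, v in basal.offsets.items()},
        }

    if "network" in config.stages:
        regulon: net.RegulonTable = _require(data, "regulon", "network")
        g = net.build_tf_graph(regulon)
        stats_table = net.network_statistics(regulon)
        stats_table.to_csv(out / "network_statistics.csv", index=False)
        net_report: dict[str, Any] = {
            "n_regulators": g.number_of_nodes(),
            "component_fraction": net.component_fraction(g),
        }
        if g.number_of_nodes() >= 2:
            f0 = net.pair_connectivity(g)
            net_report["pair_connectivity"] = f0
            removals = []
            ko_regs = sorted({ks.regulator for ks in (config.simulate.ko_specs if config.simulate else ())}
                             | set(config.inputs.get("remove", ())))
            for tf in ko_regs:
                if tf not in g or g.number_of_nodes() < 3:
                    continue
                try:
                    f1, drop = net.removal_impact(g, tf)
                except DegenerateStatisticError:
                    continue
                removals.append({"tf": tf, "connectivity_after": f1,
                                 "relative_drop_percent": drop})
            if removals:
                pd.DataFrame(removals).to_csv(out / "removal_impact.csv", index=False)
            net_report["removal_impact"] = removals
        logger.info("stage=network n_nodes=%d", g.number_of_nodes())
        report["network"] = net_report

    call_matrix = None
    if "plates" in config.stages:
        plates_in: dict = _require(data, "plates", "plates")
        call_matrix = plt.GrowthCallMatrix.from_plates(plates_in, alpha=thr.alpha)
        call_matrix.calls.rename_axis("strain").to_csv(out / "growth_calls.csv")
        plate_report: dict[str, Any] = {
            "n_strains": int(call_matrix.calls.shape[0]),
            "n_conditions": int(call_matrix.calls.shape[1]),
            "calls_per_strain": {s: int(v) for s, v in call_matrix.calls.sum(axis=1).items()},
        }
        if "wt" in call_matrix.calls.index:
            comparisons = {}
            for strain in call_matrix.calls.index:
                if strain == "wt":
                    continue
                comp = plt.compare_calls(
                    call_matrix.calls.loc["wt"], call_matrix.calls.loc[strain],
                    call_matrix.conditions,
                )
                comparisons[strain] = {
                    "n_gained": len(comp["gained"]), "n_lost": len(comp["lost"]),
                    "loss_percent_by_category": comp["loss_percent_by_category"],
                }
            plate_report["vs_wildtype"] = comparisons
        if call_matrix.calls.shape[0] >= 3:
            try:
                scores, loadings, var_frac = plt.pca_binary(call_matrix.calls)
                scores.rename_axis("strain").to_csv(out / "pca_scores.csv")
                loadings.rename_axis("condition").to_csv(out / "pca_loadings.csv")
                plate_report["pca_variance_fractions"] = [float(v) for v in var_frac[:5]]
            except InvalidSpecError:
                pass
        logger.info("stage=plates n_strains=%d", call_matrix.calls.shape[0])
        report["plates"] = plate_report

    convergence: dict[str, pd.DataFrame] = {}
    if "mutations" in config.stages:
        table: mut.MutationTable = _require(data, "mutations", "mutations")
        mut_report: dict[str, Any] = {}
        kos = sorted(set(table.records["ko"])) if len(table.records) else []
        for ko in kos:
            conv = mut.convergent_mutations(
                table, ko, min_lineages=thr.min_lineages,
                frequency_floor=thr.frequency_floor,
            )
            convergence[ko] = conv
            mut_report[ko] = {
                "convergent_genes": {row.gene: int(row.n_lineages)
                                     for row in conv.itertuples()},
            }
        if kos:
            pd.concat(
                [c.assign(ko=k) for k, c in convergence.items()], ignore_index=True
            ).to_csv(out / "convergent_mutations.csv", index=False)
        if len(table.records):
            jaccards = []
            recs = table.records
            for (ko, lineage), grp in recs.groupby(["ko", "lineage"]):
                iso = grp[(grp["sample_type"] == "isolate") & (grp["stage"] == "endpoint")]
                pop = grp[grp["sample_type"] == "population"]
                if len(iso) or len(pop):
                    try:
                        jaccards.append(mut.jaccard_agreement(iso, pop))
                    except DegenerateStatisticError:
                        pass
            if jaccards:
                mut_report["mean_jaccard_isolate_vs_population"] = float(np.mean(jaccards))
            mean_count, per_strain = mut.mutation_summary(table)
            mut_report["mean_mutations_per_isolate"] = mean_count
        logger.info("stage=mutations n_kos=%d", len(kos))
        report["mutations"] = mut_report

    if "classify" in config.stages:
        if basal is None:
            raise MissingInputError("stage 'classify' requires the 'basal' stage")
        regulon: net.RegulonTable = _require(data, "regulon", "classify")
        rates: pd.DataFrame = _require(data, "growth_rates", "classify")
        d = data["decomposition"]
        x = data["expression"]
        refs = x.reference_ids
        wt_ids = list(x.samples.index[x.samples["is_wildtype"].astype(bool)])
        if not wt_ids:
            raise MissingInputError("stage 'classify' requires wildtype samples")
        im_of_reg = {d.regulator_of(im): im for im in d.imodulons}
        members = {im: imod.member_genes(d.M[im]) for im in d.imodulons}
        rows = []
        for ko in rates.index:
            if ko not in im_of_reg:
                logger.warning("knockout %s has no linked iModulon; skipped", ko)
                continue
            im = im_of_reg[ko]
            wt_activity = float(basal.A_basal.loc[im, wt_ids].mean())
            threshold = sel.default_activity_threshold(
                basal.A_basal.loc[im, refs], fraction=thr.activity_fraction
            )
            recovered = float(rates.loc[ko, "evolved_relative_rate"]) >= thr.recovery
            # regulator-specific targets: the KO's regulon, regulators of
            # iModulons overlapping the KO's own, and configured partners
            # (post-transcriptional actors the regulon table cannot list)
            overlap_regs = {
                d.regulator_of(im2)
                for im2 in d.imodulons
                if im2 != im and members[im2] & members[im]
            } - {""}
            specific_set = (regulon.targets_of(ko) | {ko} | overlap_regs
                            | set(config.convergence_partners.get(ko, ())))
            conv = convergence.get(ko)
            conv_genes = set(conv["gene"]) if conv is not None else set()
            specific = bool(conv_genes & specific_set)
            category = sel.classify_ko(wt_activity, threshold, specific, recovered)
            rows.append({
                "ko": ko, "wt_basal_activity": wt_activity,
                "activity_threshold": threshold, "growth_recovered": recovered,
                "regulator_specific_convergence": specific, "category": category,
            })
        cls_table = pd.DataFrame(rows)
        cls_table.to_csv(out / "classification.csv", index=False)
        logger.info("stage=classify n_kos=%d", len(rows))
        report["classify"] = {r["ko"]: {
            "category": r["category"],
            "wt_basal_activity": r["wt_basal_activity"],
            "growth_recovered": bool(r["growth_recovered"]),
            "regulator_specific_convergence": bool(r["regulator_specific_convergence"]),
        } for r in rows}
        if truth is not None:
            report["classify_matches_ground_truth"] = {
                ko: (report["classify"].get(ko, {}).get("category") == cat)
                for ko, cat in truth.true_category.items()
            }

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
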