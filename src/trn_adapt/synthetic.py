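"""Synthetic study generator with recorded ground truth.

Emulates, with known structure, every input of a regulator knockout-and-
evolve (KO-ALE) study:

* a transcriptional regulatory network (regulator -> target edges with
  activation/repression/dual signs, optional hub regulators, and a reserved
  set of sole-regulator genes);
* a log-scale expression compendium generated from the ICA model
  ``X = M @ A + noise``, where each iModulon's gene weights sit on one
  regulator's regulon and each raw activity row encodes a latent
  non-negative "basal" activity through a hidden sign convention (the
  ground-truth direction).  Knockout samples pin the knocked-out
  regulator's iModulon to its no-activity extreme;
* kinetic phenotyping plates (logistic growth curves over a flat baseline
  plus Gaussian noise, with negative-control wells);
* mutation tables across independent evolution lineages, with planted
  convergent genes and Poisson background mutations;
* a gene -> growth-defect table and per-knockout evolved growth rates.

Every generator draws from its own stream spawned from the single study
seed, so modules can be regenerated independently and a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from trn_adapt.errors import InvalidSpecError
from trn_adapt.imodulons import Decomposition, ExpressionMatrix, write_decomposition, write_expression
from trn_adapt.mutations import COLUMNS as MUTATION_COLUMNS, MutationTable
from trn_adapt.network import RegulonTable
from trn_adapt.plates import PlateKinetics
from trn_adapt.selection import GrowthImpactTable

#: per-generator stream indices spawned from the study seed
_STREAMS = {
    "trn": 0,
    "expression": 1,
    "plate": 2,
    "mutations": 3,
    "impacts": 4,
    "rates": 5,
    "perturb": 6,
    "calls": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class KnockoutSpec:
    """One regulator knockout archetype within a synthetic study.

    ``effect_size`` is the wildtype basal activity of the regulator-linked
    iModulon on the growth condition (activity units): near zero means the
    regulator is inactive on that condition.  ``convergent_genes`` are
    planted to recur across lineages; ``recovered`` states whether the
    evolved strain regains wildtype-like growth.
    """

    regulator: str
    effect_size: float
    recovered: bool = True
    convergent_genes: tuple[str, ...] = ()
    n_lineages: int = 6
    convergence_rate: float = 1.0
    initial_growth_defect: float = 0.3


@dataclass(frozen=True)
class PlateSpec:
    n_wells: int = 96
    n_control_wells: int = 2
    n_timepoints: int = 97  # 48 h read every 30 min
    growth_effect: float = 50.0
    noise_sd: float = 1.0
    growth_fraction: float = 0.5
    total_hours: float = 48.0


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Full parameterization of a synthetic KO-ALE study.

    ``n_genes`` counts non-regulator target genes; the gene universe is
    the TFs plus these targets.  Densities are per ordered (TF, gene) or
    (TF, TF) pair.  ``hub_tfs`` are forced to an out-degree at least five
    times the median TF out-degree.
    """

    n_tfs: int = 20
    n_genes: int = 200
    tf_target_density: float = 0.06
    tf_tf_density: float = 0.08
    hub_tfs: tuple[str, ...] = ()
    n_reference_samples: int = 100
    n_imodulons: int = 10
    noise_sd: float = 0.25
    ko_specs: tuple[KnockoutSpec, ...] = ()
    plate_spec: PlateSpec = field(default_factory=PlateSpec)
    seed: int = 0
    # structural knobs with field-realistic defaults
    sole_target_fraction: float = 0.10
    p_repression: float = 0.30
    p_dual: float = 0.05
    activity_scale: float = 5.0
    activity_noise_sd: float = 0.0
    background_mutation_rate: float = 3.0
    high_impact_fraction: float = 0.2
    n_wildtype_samples: int = 4
    n_ko_samples: int = 2

    def validate(self) -> None:
        if self.n_tfs < 1 or self.n_genes < 1:
            raise InvalidSpecError("n_tfs and n_genes must be positive")
        if self.n_tfs > self.n_genes:
            raise InvalidSpecError("n_tfs must not exceed n_genes")
        for name in ("tf_target_density", "tf_tf_density", "sole_target_fraction",
                     "p_repression", "p_dual", "high_impact_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidSpecError(f"{name} must lie in [0, 1]")
        if self.n_reference_samples < 1 or self.n_imodulons < 1:
            raise InvalidSpecError("sample and iModulon counts must be positive")
        if self.n_imodulons > self.n_tfs:
            raise InvalidSpecError("n_imodulons must not exceed n_tfs")
        if self.noise_sd < 0 or self.activity_noise_sd < 0:
            raise InvalidSpecError("noise scales must be non-negative")

    @property
    def tf_ids(self) -> list[str]:
        return [f"tf{i + 1:03d}" for i in range(self.n_tfs)]

    @property
    def target_ids(self) -> list[str]:
        return [f"g{i + 1:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    true_directions: dict = field(default_factory=dict)
    true_growth_calls: pd.DataFrame | None = None
    true_convergent_genes: dict = field(default_factory=dict)
    true_category: dict = field(default_factory=dict)
    true_imodulon_correspondence: dict | None = None
    imodulon_of_regulator: dict = field(default_factory=dict)
    wt_basal_activity: dict = field(default_factory=dict)
    activity_thresholds: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_directions": {k: int(v) for k, v in self.true_directions.items()},
            "true_growth_calls": (
                None if self.true_growth_calls is None
                else {s: {c: int(v) for c, v in row.items()}
                      for s, row in self.true_growth_calls.iterrows()}
            ),
            "true_convergent_genes": {k: sorted(v) for k, v in self.true_convergent_genes.items()},
            "true_category": dict(self.true_category),
            "true_imodulon_correspondence": self.true_imodulon_correspondence,
            "imodulon_of_regulator": dict(self.imodulon_of_regulator),
            "wt_basal_activity": {k: float(v) for k, v in self.wt_basal_activity.items()},
            "activity_thresholds": {k: float(v) for k, v in self.activity_thresholds.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# TRN


def generate_trn(spec: SyntheticStudySpec) -> RegulonTable:
    """Random signed regulator->target network with hubs and sole-regulator genes.

    The last ``sole_target_fraction`` of target genes receive exactly one
    regulator each (they are excluded from the density draws), so
    sole-regulator statistics always have material to work on.  Hub TFs are
    topped up with extra targets until their out-degree reaches five times
    the median TF out-degree.  No self-loops are generated.
    """
    spec.validate()
    rng = _rng(spec.seed, "trn")
    tfs = spec.tf_ids
    targets = spec.target_ids
    unknown_hubs = set(spec.hub_tfs) - set(tfs)
    if unknown_hubs:
        raise InvalidSpecError(f"hub_tfs not among TF ids: {sorted(unknown_hubs)}")
    n_sole = int(spec.sole_target_fraction * len(targets))
    free_targets = targets[: len(targets) - n_sole]
    sole_targets = targets[len(targets) - n_sole:]

    edges: set[tuple[str, str]] = set()
    for tf in tfs:
        hits = rng.random(len(free_targets)) < spec.tf_target_density
        edges.update((tf, g) for g, h in zip(free_targets, hits) if h)
        hits_tf = rng.random(len(tfs)) < spec.tf_tf_density
        edges.update((tf, v) for v, h in zip(tfs, hits_tf) if h and v != tf)
    for g in sole_targets:
        edges.add((tfs[rng.integers(len(tfs))], g))

    # top up hubs until out-degree >= 5x median; a couple of passes suffice
    for _ in range(5):
        outdeg = {tf: 0 for tf in tfs}
        for u, _v in edges:
            outdeg[u] += 1
        need = int(np.ceil(5 * np.median(list(outdeg.values()))))
        done = True
        for hub in spec.hub_tfs:
            deficit = need - outdeg[hub]
            if deficit > 0:
                done = False
                candidates = [g for g in free_targets + tfs
                              if g != hub and (hub, g) not in edges]
                extra = rng.choice(len(candidates), size=min(deficit, len(candidates)),
                                   replace=False)
                edges.update((hub, candidates[i]) for i in extra)
        if done:
            break

    rows = []
    p_act = 1.0 - spec.p_repression - spec.p_dual
    if p_act < 0:
        raise InvalidSpecError("p_repression + p_dual must not exceed 1")
    for u, v in sorted(edges):
        effect = rng.choice(["activation", "repression", "dual"],
                            p=[p_act, spec.p_repression, spec.p_dual])
        rows.append({"regulator": u, "target": v, "effect": effect})
    return RegulonTable(pd.DataFrame(rows, columns=["regulator", "target", "effect"]))


# ---------------------------------------------------------------------------
# Expression + decomposition


def _sample_frame(spec: SyntheticStudySpec) -> pd.DataFrame:
    """Sample metadata: reference compendium, wildtype controls, KO samples."""
    rows = []
    for i in range(spec.n_reference_samples):
        rows.append({"sample": f"ref{i + 1:04d}", "strain": "reference", "ko": "",
                     "lineage": "", "stage": "", "is_reference": True, "is_wildtype": False})
    for i in range(spec.n_wildtype_samples):
        rows.append({"sample": f"wt_{i + 1}", "strain": "wt", "ko": "",
                     "lineage": "", "stage": "unevolved", "is_reference": False,
                     "is_wildtype": True})
    for ks in spec.ko_specs:
        for i in range(spec.n_ko_samples):
            rows.append({"sample": f"{ks.regulator}_ko_{i + 1}", "strain": f"{ks.regulator}_ko",
                         "ko": ks.regulator, "lineage": "", "stage": "unevolved",
                         "is_reference": False, "is_wildtype": False})
    return pd.DataFrame(rows).set_index("sample")


def generate_expression_and_decomposition(
    spec: SyntheticStudySpec, trn: RegulonTable
) -> tuple[ExpressionMatrix, Decomposition, GroundTruth]:
    """Generate ``X = M @ A + noise`` with known directions and KO encodings.

    Each iModulon k is linked to the k-th TF; its gene weights are nonzero
    exactly on that TF's regulon (plus the TF itself).  A latent basal
    activity b >= 0 is drawn per (iModulon, sample); the raw activity row
    is ``c + b`` for hidden direction -1 and ``c - b`` for +1, so a
    knockout sample (b = 0) sits at the row minimum or maximum
    respectively.  Wildtype samples carry each knockout's ``effect_size``
    on its linked iModulon.
    """
    spec.validate()
    rng = _rng(spec.seed, "expression")
    tfs = spec.tf_ids
    genes = tfs + spec.target_ids
    imodulons = [f"im{k + 1:03d}" for k in range(spec.n_imodulons)]
    linked_tf = {im: tfs[k] for k, im in enumerate(imodulons)}
    ko_by_reg = {ks.regulator: ks for ks in spec.ko_specs}
    for reg in ko_by_reg:
        if reg not in tfs[: spec.n_imodulons]:
            raise InvalidSpecError(
                f"knockout regulator {reg!r} has no linked iModulon "
                f"(must be one of the first n_imodulons TFs)"
            )
    im_of_reg = {tf: im for im, tf in linked_tf.items()}

    samples = _sample_frame(spec)
    sample_ids = list(samples.index)

    # gene weights: regulon members get weights in [1, 2], everything else 0
    m = pd.DataFrame(0.0, index=genes, columns=imodulons)
    for im in imodulons:
        members = sorted({linked_tf[im]} | trn.targets_of(linked_tf[im]))
        m.loc[members, im] = rng.uniform(1.0, 2.0, size=len(members))

    directions = {im: int(d) for im, d in zip(imodulons, rng.choice([-1, 1], size=len(imodulons)))}
    baselines = {im: float(c) for im, c in zip(imodulons, rng.normal(0.0, 2.0, size=len(imodulons)))}

    # exponential basal activities: most reference samples show little
    # activity of any one iModulon, a few show a lot, and the 5th
    # percentile sits near zero (the transform's no-activity anchor)
    basal = pd.DataFrame(0.0, index=imodulons, columns=sample_ids)
    for im in imodulons:
        reg = linked_tf[im]
        b = np.empty(len(sample_ids))
        for j, s in enumerate(sample_ids):
            meta = samples.loc[s]
            if meta["is_reference"]:
                b[j] = rng.exponential(spec.activity_scale)
            elif meta["ko"] == reg:
                b[j] = 0.0
            elif meta["is_wildtype"] and reg in ko_by_reg:
                b[j] = ko_by_reg[reg].effect_size
            else:
                b[j] = spec.activity_scale
        basal.loc[im] = b

    a = pd.DataFrame(0.0, index=imodulons, columns=sample_ids)
    for im in imodulons:
        c = baselines[im]
        row = c + basal.loc[im].to_numpy() if directions[im] == -1 else c - basal.loc[im].to_numpy()
        if spec.activity_noise_sd > 0:
            row = row + rng.normal(0.0, spec.activity_noise_sd, size=row.size)
        a.loc[im] = row

    x_vals = m.to_numpy() @ a.to_numpy()
    if spec.noise_sd > 0:
        x_vals = x_vals + rng.normal(0.0, spec.noise_sd, size=x_vals.shape)
    x = ExpressionMatrix(
        values=pd.DataFrame(x_vals, index=genes, columns=sample_ids),
        samples=samples.copy(),
    )
    annotations = pd.DataFrame(
        {"regulator": [linked_tf[im] for im in imodulons],
         "annotated_direction": [directions[im] for im in imodulons]},
        index=pd.Index(imodulons, name="imodulon"),
    )
    d = Decomposition(M=m, A=a, annotations=annotations)

    truth = GroundTruth(
        true_directions=dict(directions),
        imodulon_of_regulator=dict(im_of_reg),
    )
    # ground-truth activity call: the same 10%-of-reference-max rule the
    # pipeline applies, evaluated on the latent (noise-free) basal activities
    ref_ids = [s for s in sample_ids if samples.loc[s, "is_reference"]]
    for ks in spec.ko_specs:
        im = im_of_reg[ks.regulator]
        threshold = 0.10 * float(basal.loc[im, ref_ids].max())
        truth.activity_thresholds[ks.regulator] = threshold
        truth.wt_basal_activity[ks.regulator] = float(ks.effect_size)
        truth.true_convergent_genes[ks.regulator] = set(ks.convergent_genes)
        regulon = trn.targets_of(ks.regulator) | {ks.regulator}
        specific = bool(set(ks.convergent_genes) & regulon)
        if not ks.recovered:
            truth.true_category[ks.regulator] = "iv"
        elif ks.effect_size < threshold:
            truth.true_category[ks.regulator] = "i"
        elif specific:
            truth.true_category[ks.regulator] = "iii"
        else:
            truth.true_category[ks.regulator] = "ii"
    return x, d, truth


def perturb_decomposition(
    d: Decomposition, noise_sd: float = 0.1, seed: int = 0
) -> tuple[Decomposition, dict]:
    """Permute, sign-flip and noise a decomposition's gene weights.

    Columns of M are unit-normalized, permuted, flipped with probability
    1/2 and perturbed with Gaussian weight noise of sd ``noise_sd``; the A
    rows are permuted and flipped consistently.  Returns the perturbed
    decomposition and the true correspondence {original -> perturbed}.
    """
    rng = np.random.default_rng(seed)
    k = d.M.shape[1]
    perm = rng.permutation(k)
    flips = rng.choice([-1.0, 1.0], size=k)
    new_names = [f"p{j + 1:03d}" for j in range(k)]
    m_new = pd.DataFrame(index=d.M.index, columns=new_names, dtype=float)
    a_new = pd.DataFrame(index=new_names, columns=d.A.columns, dtype=float)
    correspondence = {}
    for new_pos, orig_pos in enumerate(perm):
        orig = d.M.columns[orig_pos]
        col = d.M[orig].to_numpy(dtype=float)
        norm = np.linalg.norm(col)
        col = col / norm if norm > 0 else col
        col = flips[new_pos] * col + rng.normal(0.0, noise_sd, size=col.size)
        m_new[new_names[new_pos]] = col
        a_new.loc[new_names[new_pos]] = flips[new_pos] * d.A.loc[orig].to_numpy(dtype=float)
        correspondence[orig] = new_names[new_pos]
    ann = pd.DataFrame({"regulator": [""] * k}, index=pd.Index(new_names, name="imodulon"))
    return Decomposition(M=m_new, A=a_new, annotations=ann), correspondence


# ---------------------------------------------------------------------------
# Plates


def generate_plate(
    plate_spec: PlateSpec, seed: int = 0, growth_wells: Sequence[bool] | None = None
) -> tuple[PlateKinetics, pd.Series]:
    """One kinetic plate: logistic growth wells over a flat noisy baseline.

    Growth wells follow ``baseline + K / (1 + exp(-r (t - t0)))`` with the
    carrying capacity K equal to ``growth_effect`` and per-well random rate
    and lag; non-growth and negative-control wells are baseline plus noise.
    Returns the plate and the ground-truth growth call per tested well.
    """
    ps = plate_spec
    if ps.n_control_wells < 2:
        raise InvalidSpecError("need >= 2 negative-control wells")
    if ps.n_wells <= ps.n_control_wells:
        raise InvalidSpecError("plate must contain tested wells")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, ps.total_hours, ps.n_timepoints)
    n_tested = ps.n_wells - ps.n_control_wells
    categories = ["C", "N", "S", "P"]
    wells, traces, truth = [], [], {}
    if growth_wells is None:
        grow_flags = rng.random(n_tested) < ps.growth_fraction
    else:
        grow_flags = np.asarray(list(growth_wells), dtype=bool)
        if grow_flags.size != n_tested:
            raise InvalidSpecError("growth_wells length must equal tested well count")
    baseline = 10.0
    for i in range(n_tested):
        cat = categories[i % len(categories)]
        well = f"W{i + 1:03d}"
        substrate = f"{cat}_substrate_{i // len(categories) + 1:02d}"
        wells.append({"well": well, "substrate": substrate, "category": cat,
                      "is_control": False})
        if grow_flags[i]:
            rate = rng.uniform(0.25, 0.5)
            lag = rng.uniform(8.0, 20.0)
            curve = baseline + ps.growth_effect / (1.0 + np.exp(-rate * (t - lag)))
        else:
            curve = np.full_like(t, baseline)
        noise = rng.normal(0.0, ps.noise_sd, size=t.size) if ps.noise_sd > 0 else 0.0
        traces.append(curve + noise)
        truth[substrate] = int(grow_flags[i])
    for i in range(ps.n_control_wells):
        well = f"CTRL{i + 1:02d}"
        wells.append({"well": well, "substrate": f"negative_control_{i + 1}",
                      "category": "control", "is_control": True})
        noise = rng.normal(0.0, ps.noise_sd, size=t.size) if ps.noise_sd > 0 else 0.0
        traces.append(np.full_like(t, baseline) + noise)
    meta = pd.DataFrame(wells).set_index("well")
    sig = pd.DataFrame(np.vstack(traces), index=meta.index,
                       columns=[format(v, "g") for v in t])
    plate = PlateKinetics(wells=meta, signal=sig, timepoints=t)
    return plate, pd.Series(truth, name="true_call")


def generate_study_plates(
    spec: SyntheticStudySpec,
) -> tuple[dict, pd.DataFrame]:
    """One plate per strain (wildtype + evolved knockouts), shared conditions.

    Strains share the substrate layout; each strain grows on a random
    subset of substrates so cross-strain gains/losses and PCA have
    structure.  Returns {strain: plate} and the true call matrix.
    """
    rng = _rng(spec.seed, "plate")
    strains = ["wt"] + [f"{ks.regulator}_ko" for ks in spec.ko_specs]
    plates, rows = {}, {}
    n_tested = spec.plate_spec.n_wells - spec.plate_spec.n_control_wells
    for strain in strains:
        grow = rng.random(n_tested) < spec.plate_spec.growth_fraction
        plate, truth = generate_plate(
            spec.plate_spec, seed=int(rng.integers(2**31)), growth_wells=grow
        )
        plates[strain] = plate
        rows[strain] = truth
    return plates, pd.DataFrame(rows).T


def generate_binary_call_matrix(
    n_strains: int = 20,
    n_conditions: int = 96,
    nitrogen_fraction: float = 0.4,
    flip_prob: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Binary call matrix dominated by a nitrogen-utilization factor.

    Half the strains are nitrogen utilizers; nitrogen conditions track
    that trait (with a small flip probability) while other conditions are
    common background.  Returns (calls, condition metadata, generating
    factor over conditions) — the factor is the nitrogen-column indicator,
    which PCA should recover as its leading loading vector.
    """
    rng = np.random.default_rng(seed)
    n_nitro = int(nitrogen_fraction * n_conditions)
    cats = ["N"] * n_nitro + ["C"] * (n_conditions - n_nitro)
    conditions = [f"{c}_{i + 1:03d}" for i, c in enumerate(cats)]
    factor = np.array([1.0 if c == "N" else 0.0 for c in cats])
    utilizer = rng.permutation(np.arange(n_strains) < n_strains // 2)
    calls = np.zeros((n_strains, n_conditions), dtype=int)
    for i in range(n_strains):
        for j in range(n_conditions):
            if cats[j] == "N":
                p = 0.95 if utilizer[i] else 0.05
            else:
                p = 0.8
            calls[i, j] = int(rng.random() < p)
    flips = rng.random(calls.shape) < flip_prob
    calls = np.where(flips, 1 - calls, calls)
    meta = pd.DataFrame({"category": cats}, index=pd.Index(conditions, name="condition"))
    return (
        pd.DataFrame(calls, index=[f"strain_{i + 1:02d}" for i in range(n_strains)],
                     columns=conditions),
        meta,
        factor,
    )


# ---------------------------------------------------------------------------
# Mutations, growth impacts, growth rates


def generate_mutation_tables(spec: SyntheticStudySpec) -> MutationTable:
    """Mutation records across lineages with planted convergent genes.

    For each knockout, each planted convergent gene is mutated in at least
    two lineages (binomial with the knockout's ``convergence_rate``,
    floored at 2); background mutations arrive per lineage as a Poisson
    count over random genes.  Endpoint isolates (frequency 1) are paired
    with population samples that carry most of the same mutations at
    frequencies in (0, 1].
    """
    if not spec.ko_specs:
        raise InvalidSpecError("ko_specs is empty")
    rng = _rng(spec.seed, "mutations")
    all_genes = spec.tf_ids + spec.target_ids
    rows = []

    def add(ko, lineage, stage, sample_type, gene, position, allele, frequency):
        rows.append({
            "strain": f"{ko}_{lineage}_{stage}_{sample_type[:3]}",
            "ko": ko, "lineage": lineage, "stage": stage, "sample_type": sample_type,
            "gene": gene, "position": int(position), "allele": allele,
            "frequency": float(frequency),
        })

    bases = "ACGT"
    for ks in spec.ko_specs:
        lineages = [f"A{i + 1}" for i in range(ks.n_lineages)]
        gene_pos = {g: int(rng.integers(1, 4_600_000)) for g in set(ks.convergent_genes)}
        # planted convergence: >= 2 lineages per convergent gene
        for gene in ks.convergent_genes:
            n_hit = max(2, int(rng.binomial(ks.n_lineages, ks.convergence_rate)))
            n_hit = min(n_hit, ks.n_lineages)
            hit = rng.choice(ks.n_lineages, size=n_hit, replace=False)
            for li in hit:
                pos = gene_pos[gene] + int(rng.integers(0, 50))
                ref, alt = rng.choice(list(bases), size=2, replace=False)
                allele = f"{ref}>{alt}"
                add(ks.regulator, lineages[li], "endpoint", "isolate", gene, pos, allele, 1.0)
                add(ks.regulator, lineages[li], "endpoint", "population", gene, pos, allele,
                    rng.uniform(0.6, 1.0))
        # background mutations, independent per lineage; each lineage draws
        # from its own slice of the gene pool so background hits never
        # recur across lineages and the planted convergent sets stay the
        # exhaustive ground truth
        background_pool = [g for g in all_genes if g not in set(ks.convergent_genes)]
        shuffled = list(rng.permutation(background_pool))
        slice_size = len(shuffled) // max(1, ks.n_lineages)
        for li, lineage in enumerate(lineages):
            pool = shuffled[li * slice_size:(li + 1) * slice_size]
            n_bg = min(rng.poisson(spec.background_mutation_rate), len(pool))
            genes_bg = rng.choice(pool, size=n_bg, replace=False) if n_bg else []
            for gene in genes_bg:
                pos = int(rng.integers(1, 4_600_000))
                ref, alt = rng.choice(list(bases), size=2, replace=False)
                allele = f"{ref}>{alt}"
                add(ks.regulator, lineage, "endpoint", "isolate", gene, pos, allele, 1.0)
                if rng.random() < 0.8:  # population usually sees the isolate's mutations
                    add(ks.regulator, lineage, "endpoint", "population", gene, pos, allele,
                        rng.uniform(0.05, 1.0))
    if rows:
        df = pd.DataFrame(rows)[list(MUTATION_COLUMNS)]
        df = df.drop_duplicates(subset=["strain", "sample_type", "stage", "position", "allele"])
    else:
        df = pd.DataFrame(columns=list(MUTATION_COLUMNS))
    return MutationTable(df.reset_index(drop=True))


def generate_growth_impacts(trn: RegulonTable, spec: SyntheticStudySpec) -> GrowthImpactTable:
    """gene -> relative growth defect in [0, 1]; a configurable share are high-impact."""
    rng = _rng(spec.seed, "impacts")
    genes = sorted(set(trn.records["regulator"]) | set(trn.records["target"]))
    high = rng.random(len(genes)) < spec.high_impact_fraction
    vals = np.where(high, rng.uniform(0.5, 1.0, len(genes)), rng.uniform(0.0, 0.3, len(genes)))
    return GrowthImpactTable(pd.Series(vals, index=pd.Index(genes, name="gene")))


def generate_growth_rates(spec: SyntheticStudySpec) -> pd.DataFrame:
    """Per-knockout growth summary: initial defect and evolved rate relative to wildtype.

    Recovered knockouts end within 95-105% of the wildtype rate;
    non-recovering ones plateau at 40-80%.
    """
    rng = _rng(spec.seed, "rates")
    rows = []
    for ks in spec.ko_specs:
        evolved = rng.uniform(0.96, 1.05) if ks.recovered else rng.uniform(0.4, 0.8)
        rows.append({"ko": ks.regulator,
                     "initial_growth_defect": ks.initial_growth_defect,
                     "evolved_relative_rate": float(evolved)})
    return pd.DataFrame(rows).set_index("ko")


# ---------------------------------------------------------------------------
# Whole-study bundle


@dataclass
class SimulatedStudy:
    spec: SyntheticStudySpec
    trn: RegulonTable
    expression: ExpressionMatrix
    decomposition: Decomposition
    plates: dict
    mutations: MutationTable
    growth_impacts: GrowthImpactTable
    growth_rates: pd.DataFrame
    ground_truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict:
        """Write every artifact in its consuming module's dialect; return paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "regulon": out / "regulon.tsv",
            "expression": out / "expression.tsv",
            "samples": out / "samples.csv",
            "m": out / "M.csv",
            "a": out / "A.csv",
            "annotations": out / "annotations.csv",
            "mutations": out / "mutations.tsv",
            "growth_impacts": out / "growth_impacts.csv",
            "growth_rates": out / "growth_rates.csv",
            "ground_truth": out / "ground_truth.json",
        }
        self.trn.to_tsv(paths["regulon"])
        write_expression(self.expression, paths["expression"], paths["samples"])
        write_decomposition(self.decomposition, paths["m"], paths["a"], paths["annotations"])
        self.mutations.to_tsv(paths["mutations"])
        self.growth_impacts.to_csv(paths["growth_impacts"])
        self.growth_rates.to_csv(paths["growth_rates"])
        self.ground_truth.to_json(paths["ground_truth"])
        for strain, plate in self.plates.items():
            p = out / f"plate_{strain}.csv"
            plate.to_csv(p)
            paths[f"plate_{strain}"] = p
        return {k: str(v) for k, v in paths.items()}


def simulate_study(spec: SyntheticStudySpec) -> SimulatedStudy:
    """Generate every input of a knockout-adaptation study with ground truth."""
    spec.validate()
    trn = generate_trn(spec)
    x, d, truth = generate_expression_and_decomposition(spec, trn)
    plates, true_calls = generate_study_plates(spec)
    truth.true_growth_calls = true_calls
    muts = (generate_mutation_tables(spec) if spec.ko_specs
            else MutationTable(pd.DataFrame(columns=list(MUTATION_COLUMNS))))
    impacts = generate_growth_impacts(trn, spec)
    rates = generate_growth_rates(spec)
    return SimulatedStudy(
        spec=spec, trn=trn, expression=x, decomposition=d, plates=plates,
        mutations=muts, growth_impacts=impacts, growth_rates=rates,
        ground_truth=truth,
    )


def archetype_spec(seed: int = 0, **overrides) -> SyntheticStudySpec:
    """A study spec containing the four knockout adaptation archetypes.

    tf001: inactive on the condition, recovers (category i).
    tf002: active, recovers without regulator-specific mutations (ii).
    tf003: active, recovers through a planted convergent mutation in its
           own regulon (iii).
    tf004: active hub, does not recover (iv).
    """
    base = SyntheticStudySpec(seed=seed, hub_tfs=("tf004",))
    trn = generate_trn(base)
    regulon3 = sorted(trn.targets_of("tf003"))
    if not regulon3:
        raise InvalidSpecError("archetype TRN left tf003 without targets")
    convergent = (regulon3[0],)
    off_regulon = sorted(set(base.target_ids) - trn.targets_of("tf002")
                         - trn.targets_of("tf003"))[0]
    kos = (
        KnockoutSpec("tf001", effect_size=0.0, recovered=True),
        KnockoutSpec("tf002", effect_size=8.0, recovered=True,
                     convergent_genes=(off_regulon,)),
        KnockoutSpec("tf003", effect_size=8.0, recovered=True,
                     convergent_genes=convergent),
        KnockoutSpec("tf004", effect_size=8.0, recovered=False),
    )
    return SyntheticStudySpec(seed=seed, hub_tfs=("tf004",), ko_specs=kos, **overrides)
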