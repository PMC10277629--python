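"""Synthetic longitudinal whole-blood RNA-seq cohorts with known ground truth.

The generator emulates a prospective pregnancy cohort: a small number of
subjects sampled repeatedly from a pre-pregnancy baseline (T0) through the
trimesters (T1..T3) into the postpartum period (PP3..PP9).  Bulk counts are
produced as library-size-scaled mixtures of cell-type expression signatures,
so that two distinct mechanisms can move a gene's observed expression:

* **composition** — the mixing proportions of cell types drift over time, so
  marker genes of an expanding type rise in the bulk signal without any
  change in per-cell transcription;
* **regulation** — a gene-level multiplicative effect exp(rho_{g,t}) applied
  on top of the mixture, representing genuine transcriptional regulation.

Every planted effect is recorded in a :class:`SimTruth` ledger so that
downstream mechanism classification can be scored against the truth.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = ("T0", "T1", "T2", "T3", "PP3", "PP6", "PP9")
"""Ordered sampling schedule: baseline, trimesters, and months postpartum."""

DEFAULT_CELL_TYPES = (
    "neutrophils",
    "cd4_t_cells",
    "cd8_t_cells",
    "b_cells",
    "nk_cells",
    "monocytes",
    "plasma_cells",
    "dendritic_cells",
)

#: proportion fold-change (vs T0) above which a cell type counts as having a
#: non-constant trajectory for truth labeling.  Shifting one type moves every
#: other type slightly through simplex renormalization; those passive moves
#: are too small to surface as marker-gene expression changes and are not
#: counted as composition effects.
CHANGE_FOLD_THRESHOLD = 1.5

TRUTH_CLASSES = ("null", "composition", "regulation", "mixed")


@dataclasses.dataclass(frozen=True)
class SignatureMatrix:
    """Cell-type expression signature on the linear scale.

    ``values`` is genes x cell types; ``markers`` maps each cell type to the
    genes designated as its markers (expression at least ``marker_fold`` times
    higher in that type than in any other).
    """

    values: pd.DataFrame
    markers: Mapping[str, tuple[str, ...]]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns

    def marker_of(self) -> pd.Series:
        """Per-gene cell type the gene marks, or '' for non-markers."""
        out = pd.Series("", index=self.genes, dtype=object)
        for ct, genes in self.markers.items():
            out.loc[list(genes)] = ct
        return out


@dataclasses.dataclass(frozen=True)
class CompositionTrajectories:
    """True mixing proportions per (subject, timepoint); rows on the simplex.

    ``proportions`` is indexed by a (subject_id, timepoint) MultiIndex with
    one column per cell type.
    """

    proportions: pd.DataFrame
    timepoints: tuple[str, ...]

    @property
    def subjects(self) -> list[str]:
        return list(self.proportions.index.get_level_values(0).unique())

    @property
    def cell_types(self) -> pd.Index:
        return self.proportions.columns

    def at(self, subject: str, timepoint: str) -> np.ndarray:
        return self.proportions.loc[(subject, timepoint)].to_numpy(float)


@dataclasses.dataclass(frozen=True)
class RegulationPlan:
    """Planted per-gene regulation effects and noise parameters.

    rho: genes x timepoints natural-log multiplicative effects (rho at T0 = 0).
    tau: SD of the gene-by-subject log-normal random effect.
    phi: per-gene NB dispersion, variance mu + phi mu^2.
    lib_sizes: subjects x timepoints target library sizes.
    """

    rho: pd.DataFrame
    tau: float
    phi: pd.Series
    lib_sizes: pd.DataFrame

    def __post_init__(self) -> None:
        t0 = self.rho.get("T0")
        if t0 is None or not np.allclose(t0.to_numpy(float), 0.0):
            raise ValueError("regulation effects must be zero at the T0 baseline")
        if (self.phi.to_numpy(float) <= 0).any():
            raise ValueError("NB dispersion phi must be positive for every gene")
        if (self.lib_sizes.to_numpy(float) <= 0).any():
            raise ValueError("library sizes must be positive")


@dataclasses.dataclass(frozen=True)
class SimTruth:
    """Ground-truth ledger for one simulated cohort."""

    table: pd.DataFrame  # per gene: class, marker_of, marker_of_changing_type, regulated_timepoints
    proportions: pd.DataFrame  # true per-sample proportions (samples x types)
    seed: int


@dataclasses.dataclass(frozen=True)
class AgeParams:
    mean: float = 28.9
    sd: float = 1.0


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_signature(
    n_genes: int,
    n_cell_types: int,
    markers_per_type: int = 25,
    marker_fold: float = 50.0,
    seed: int = 0,
    cell_types: Sequence[str] | None = None,
) -> SignatureMatrix:
    """Draw a nonnegative genes x cell-types signature with designated markers.

    Background expression is log-normal; each cell type gets
    ``markers_per_type`` marker genes whose value in that type is set to
    ``marker_fold`` times the gene's maximum across the other types.
    """
    if n_genes <= 0 or n_cell_types <= 0 or markers_per_type <= 0:
        raise ValueError("dimensions must be positive")
    if marker_fold < 1:
        raise ValueError("marker_fold must be >= 1")
    if marker_fold < 5:
        raise ValueError("marker_fold must be >= 5 so markers satisfy the signature invariant")
    if n_genes < n_cell_types * markers_per_type:
        raise ValueError(
            f"n_genes={n_genes} cannot host {n_cell_types} x {markers_per_type} markers"
        )
    if cell_types is None:
        if n_cell_types <= len(DEFAULT_CELL_TYPES):
            cell_types = DEFAULT_CELL_TYPES[:n_cell_types]
        else:
            cell_types = tuple(f"cell_type_{i+1:02d}" for i in range(n_cell_types))
    elif len(cell_types) != n_cell_types:
        raise ValueError("cell_types length must equal n_cell_types")

    rng = _rng(seed)
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene")
    values = rng.lognormal(mean=math.log(5.0), sigma=1.2, size=(n_genes, n_cell_types))

    order = rng.permutation(n_genes)
    markers: dict[str, tuple[str, ...]] = {}
    pos = 0
    for c, ct in enumerate(cell_types):
        idx = order[pos : pos + markers_per_type]
        pos += markers_per_type
        other = np.delete(np.arange(n_cell_types), c)
        values[idx, c] = marker_fold * values[np.ix_(idx, other)].max(axis=1)
        markers[ct] = tuple(genes[i] for i in sorted(idx))

    df = pd.DataFrame(values, index=genes, columns=pd.Index(cell_types, name="cell_type"))
    return SignatureMatrix(values=df, markers=markers)


def _alr(p: np.ndarray) -> np.ndarray:
    # additive log-ratio with the last component as reference
    return np.log(p[:-1]) - np.log(p[-1])


def _alr_inv(z: np.ndarray) -> np.ndarray:
    e = np.exp(np.concatenate([z, [0.0]]))
    return e / e.sum()


def generate_compositions(
    n_subjects: int,
    timepoints: Sequence[str],
    baseline_alpha: Mapping[str, float],
    logit_shifts: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> CompositionTrajectories:
    """Subject-level Dirichlet baselines moved over time by ALR shifts.

    Each subject draws a baseline composition from Dirichlet(baseline_alpha).
    At each timepoint the baseline's additive log-ratio coordinates (reference
    = last cell type) are shifted by ``logit_shifts[timepoint][cell_type]``
    and mapped back to the simplex, preserving subjects' rank ordering while
    keeping every row a valid composition.
    """
    cell_types = list(baseline_alpha)
    alpha = np.array([baseline_alpha[c] for c in cell_types], float)
    if (alpha <= 0).any():
        raise ValueError("baseline_alpha entries must be positive")
    timepoints = tuple(timepoints)
    unknown = set(timepoints) - set(TIMEPOINTS)
    if unknown:
        raise ValueError(f"unknown timepoint labels: {sorted(unknown)}")
    if timepoints[0] != "T0":
        raise ValueError("timepoints must start with the T0 baseline")
    logit_shifts = logit_shifts or {}
    for tp, shifts in logit_shifts.items():
        if tp not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint in logit_shifts: {tp}")
        for ct in shifts:
            if ct not in cell_types:
                raise ValueError(f"unknown cell type in logit_shifts: {ct}")
            if ct == cell_types[-1]:
                raise ValueError(
                    "cannot shift the ALR reference type (last entry of baseline_alpha)"
                )

    rng = _rng(seed)
    subjects = [f"S{i+1:02d}" for i in range(n_subjects)]
    rows = []
    index = []
    for s in subjects:
        base = rng.dirichlet(alpha)
        z0 = _alr(base)
        for tp in timepoints:
            z = z0.copy()
            for ct, delta in logit_shifts.get(tp, {}).items():
                z[cell_types.index(ct)] += delta
            rows.append(_alr_inv(z))
            index.append((s, tp))
    props = pd.DataFrame(
        np.asarray(rows),
        index=pd.MultiIndex.from_tuples(index, names=["subject_id", "timepoint"]),
        columns=pd.Index(cell_types, name="cell_type"),
    )
    return CompositionTrajectories(proportions=props, timepoints=timepoints)


def changing_cell_types(
    compositions: CompositionTrajectories,
    fold_threshold: float = CHANGE_FOLD_THRESHOLD,
) -> list[str]:
    """Cell types whose trajectory moves materially away from its T0 level.

    A type is "changing" when the median over subjects of |log(p_t / p_T0)|
    exceeds log(fold_threshold) at some timepoint.  The threshold separates
    actively shifted types from the small passive renormalization every type
    experiences whenever any other type moves.
    """
    props = compositions.proportions
    base = props.xs("T0", level="timepoint")
    out = []
    for ct in props.columns:
        for tp in compositions.timepoints[1:]:
            at_tp = props.xs(tp, level="timepoint")[ct]
            ratio = np.abs(np.log(at_tp.to_numpy(float) / base[ct].to_numpy(float)))
            if np.median(ratio) > math.log(fold_threshold):
                out.append(ct)
                break
    return out


def truth_classes(
    signature: SignatureMatrix,
    compositions: CompositionTrajectories,
    plan: RegulationPlan,
    fold_threshold: float = CHANGE_FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Recompute per-gene truth labels from the planted inputs.

    class = composition  iff marker of a changing type and rho == 0
            regulation   iff rho != 0 and not such a marker
            mixed        iff both; null otherwise.
    """
    changing = set(changing_cell_types(compositions, fold_threshold))
    marker_of = signature.marker_of()
    is_comp = marker_of.isin(changing)
    regulated = (plan.rho.to_numpy(float) != 0.0).any(axis=1)
    is_reg = pd.Series(regulated, index=plan.rho.index).reindex(signature.genes, fill_value=False)

    cls = np.where(
        is_comp & is_reg, "mixed", np.where(is_comp, "composition", np.where(is_reg, "regulation", "null"))
    )
    reg_tps = [
        ",".join(plan.rho.columns[plan.rho.loc[g].to_numpy(float) != 0.0]) if g in plan.rho.index else ""
        for g in signature.genes
    ]
    return pd.DataFrame(
        {
            "class": cls,
            "marker_of": marker_of.to_numpy(),
            "marker_of_changing_type": is_comp.to_numpy(),
            "regulated_timepoints": reg_tps,
        },
        index=signature.genes,
    )


def generate_counts(
    signature: SignatureMatrix,
    compositions: CompositionTrajectories,
    plan: RegulationPlan,
    age_params: AgeParams = AgeParams(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw NB counts from the mixture model and return (counts, metadata, truth).

    The expected count of gene g for subject i at time t is

        mu = N_{i,t} * exp(b_{g,i}) * exp(rho_{g,t}) * share_{g,i,t}

    with share the gene's fraction of the raw signature mixture
    sum_c p_{c,i,t} S_{g,c} normalized over genes, b_{g,i} ~ N(0, tau^2), and
    counts ~ NB(mean mu, variance mu + phi_g mu^2).
    """
    genes = signature.genes
    if not genes.equals(plan.rho.index):
        raise ValueError("gene sets of signature and regulation plan disagree")
    subjects = compositions.subjects
    tps = compositions.timepoints
    if set(plan.lib_sizes.index) != set(subjects) or set(plan.lib_sizes.columns) != set(tps):
        raise ValueError("plan.lib_sizes must cover exactly the (subject, timepoint) grid")
    missing_rho = [t for t in tps if t not in plan.rho.columns]
    if missing_rho:
        raise ValueError(f"plan.rho lacks timepoints: {missing_rho}")

    rng = _rng(seed)
    S = signature.values.to_numpy(float)  # genes x types
    n_genes = len(genes)
    phi = plan.phi.reindex(genes).to_numpy(float)
    if np.isnan(phi).any():
        raise ValueError("plan.phi must cover every signature gene")

    b = rng.normal(0.0, plan.tau, size=(n_genes, len(subjects))) if plan.tau > 0 else np.zeros(
        (n_genes, len(subjects))
    )

    sample_ids, meta_rows, count_cols, true_prop_rows = [], [], [], []
    ages = {}
    for s in subjects:
        a = rng.normal(age_params.mean, age_params.sd)
        while a <= 18:
            a = rng.normal(age_params.mean, age_params.sd)
        ages[s] = a
    parity = {s: rng.choice([0, 1, 2], p=[7 / 14, 6 / 14, 1 / 14]) for s in subjects}

    for si, s in enumerate(subjects):
        for tp in tps:
            p = compositions.at(s, tp)
            mix = S @ p
            share = mix / mix.sum()
            mu = (
                plan.lib_sizes.loc[s, tp]
                * np.exp(b[:, si])
                * np.exp(plan.rho[tp].to_numpy(float))
                * share
            )
            # NB(mean mu, var mu + phi mu^2): size r = 1/phi, p = r/(r+mu)
            r = 1.0 / phi
            counts = rng.negative_binomial(r, r / (r + mu))
            sid = f"{s}_{tp}"
            sample_ids.append(sid)
            count_cols.append(counts)
            true_prop_rows.append(p)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": s,
                    "timepoint": tp,
                    "age": ages[s],
                    "parity": int(parity[s]),
                }
            )

    counts = pd.DataFrame(
        np.column_stack(count_cols), index=genes, columns=pd.Index(sample_ids, name="sample_id")
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth_table = truth_classes(signature, compositions, plan)
    true_props = pd.DataFrame(
        np.asarray(true_prop_rows), index=pd.Index(sample_ids, name="sample_id"), columns=compositions.cell_types
    )
    return counts, metadata, SimTruth(table=truth_table, proportions=true_props, seed=seed)


def default_regulation_plan(
    signature: SignatureMatrix,
    compositions: CompositionTrajectories,
    regulated_fraction: float = 0.05,
    effect_size: float = math.log(4.0),
    mixed_markers: int = 0,
    tau: float = 0.3,
    phi_range: tuple[float, float] = (0.01, 0.5),
    lib_size_mean: float = 2e6,
    lib_size_cv: float = 0.2,
    revert_postpartum: bool = True,
    seed: int = 0,
) -> RegulationPlan:
    """Build a regulation plan at the cohort's study conditions.

    Regulated genes ramp to +/- ``effect_size`` (natural log) over the
    trimesters; postpartum timepoints revert to baseline when
    ``revert_postpartum`` (expression returns to pre-pregnancy levels after
    childbirth).  ``mixed_markers`` markers of the first changing type also
    receive a regulation effect, creating genuinely mixed-mechanism genes.
    """
    rng = _rng(seed)
    genes = signature.genes
    tps = compositions.timepoints
    marker_of = signature.marker_of()
    non_markers = genes[marker_of == ""]

    n_reg = int(round(regulated_fraction * len(genes)))
    reg_genes = list(rng.choice(non_markers, size=min(n_reg, len(non_markers)), replace=False))
    changing = changing_cell_types(compositions)
    if mixed_markers and changing:
        pool = list(signature.markers[changing[0]])
        reg_genes += list(rng.choice(pool, size=min(mixed_markers, len(pool)), replace=False))

    ramp = {"T0": 0.0, "T1": 0.5, "T2": 0.8, "T3": 1.0, "PP3": 0.0, "PP6": 0.0, "PP9": 0.0}
    if not revert_postpartum:
        ramp.update({"PP3": 1.0, "PP6": 1.0, "PP9": 1.0})
    rho = pd.DataFrame(0.0, index=genes, columns=list(tps))
    signs = rng.choice([-1.0, 1.0], size=len(reg_genes))
    for g, sgn in zip(reg_genes, signs):
        for tp in tps:
            rho.loc[g, tp] = sgn * effect_size * ramp[tp]

    phi = pd.Series(
        np.exp(rng.uniform(math.log(phi_range[0]), math.log(phi_range[1]), size=len(genes))),
        index=genes,
        name="phi",
    )
    subjects = compositions.subjects
    sigma = math.sqrt(math.log(1 + lib_size_cv**2))
    libs = lib_size_mean * np.exp(
        rng.normal(-sigma**2 / 2, sigma, size=(len(subjects), len(tps)))
    )
    lib_sizes = pd.DataFrame(libs, index=subjects, columns=list(tps))
    return RegulationPlan(rho=rho, tau=tau, phi=phi, lib_sizes=lib_sizes)
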