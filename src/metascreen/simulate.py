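"""Synthetic plate-based metabolome screens with planted drug-target pairs.

The generator emulates the structure of a flow-injection MS chemical screen
in yeast: 96-well plates measured in injection order with smooth temporal
drift, a multiplicative biomass (OD600) effect, lognormal measurement
noise, replicate wells, vehicle (DMSO) and estradiol-treated wild-type
control wells on every plate, and an inducible overexpression arm measured
over an 8-concentration inducer series spanning seven orders of magnitude
plus the uninduced state.

Biology of the planted signal
-----------------------------
Each gene g carries a sparse log-intensity effect vector ``v_g``.  The
overexpression arm responds to inducer dose d through a logistic activation
``L(d) = 1 / (1 + exp(-k_g (log10 d - x0_g)))`` with ``L(0) := 0``: the
uninduced state is a pure loss-of-function phenotype, scaled by
``loss_gain`` (weak, because basal expression retains partial function),
while full induction scales ``v_g`` by ``oe_gain``:

    shift(d) = v_g * (oe_gain * L(d) - loss_gain * (1 - L(d)))

A planted drug for gene g shifts the metabolome by ``sign * potency * v_g``
plus its own sparse off-target vector ``w``: agonists (+1) push toward the
overexpression-like state, antagonists (-1) toward the loss-of-function
state, so the similarity-versus-dose series of a planted antagonist
decreases with dose and the fitted logistic slope is negative.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import MoleculeGraph
from .screen_io import META_COLUMNS, ScreenTable

__all__ = [
    "SimulationParams",
    "PlantedPair",
    "TruthTable",
    "default_doses",
    "generate_truth",
    "simulate_oe_screen",
    "simulate_drug_screen",
    "simulate_genotype_screen",
    "simulate_molecules",
    "simulate_go_annotations",
]


def default_doses() -> list[float]:
    """Uninduced plus eight inducer doses spanning seven orders of magnitude (nM)."""
    return [0.0] + list(np.logspace(0.0, 7.0, 8))


@dataclasses.dataclass
class SimulationParams:
    """Study-design parameters of the synthetic screens.

    Defaults are scaled-down study conditions: 40 genes, 200 drugs, 200
    ions, 20 planted pairs, 2 replicates, 96-well plates, two timepoints
    (1.5 h and 3 h), and drug treatments at a fixed 10 uM.
    """

    n_genes: int = 40
    n_drugs: int = 200
    n_ions: int = 200
    n_planted: int = 20
    doses: Sequence[float] = dataclasses.field(default_factory=default_doses)
    timepoints: Sequence[float] = (1.5, 3.0)
    replicates: int = 2
    plate_size: int = 96
    controls_per_plate: int = 6
    drift_amplitude: float = 0.10      # fractional intensity drift over a batch
    od_effect_scale: float = 1.0       # mean per-ion exponent of the OD600 effect
    noise_cv: float = 0.15             # lognormal measurement noise CV
    effect_sparsity: float = 0.15      # fraction of ions a gene or drug perturbs
    oe_gain: float = 1.0               # A: effect scale at full induction
    loss_gain: float = 0.15            # C: effect scale of the uninduced state
    antagonist_fraction: float = 0.60
    drug_dose_nm: float = 10_000.0     # 10 uM, the fixed screening concentration
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted > min(self.n_drugs, self.n_genes):
            raise ValueError("n_planted exceeds n_drugs or n_genes")
        doses = list(self.doses)
        if doses != sorted(doses) or doses[0] != 0.0:
            raise ValueError("doses must be ascending with doses[0] == 0")
        if not (0 < self.effect_sparsity <= 1):
            raise ValueError("effect_sparsity must be in (0, 1]")
        if self.replicates < 1 or self.plate_size < 2:
            raise ValueError("replicates and plate_size must be positive")
        if self.controls_per_plate < 3:
            raise ValueError("need >= 3 control wells per plate")

    @property
    def positive_doses(self) -> list[float]:
        return [d for d in self.doses if d > 0]

    def inflection_range(self) -> tuple[float, float]:
        """Interior of the positive dose range, in log10 nM."""
        if not self.positive_doses:
            return 2.0, 2.0  # uninduced-only design: inflection is irrelevant
        lo = math.log10(min(self.positive_doses))
        hi = math.log10(max(self.positive_doses))
        if hi - lo <= 2:
            return lo, hi
        return lo + 1.0, hi - 1.0


@dataclasses.dataclass(frozen=True)
class PlantedPair:
    gene: str
    drug: str
    mode: str                 # "agonist" | "antagonist"
    potency: float            # effect-scale multiplier on the drug side
    inflection_log10nm: float  # x0 of the induction logistic
    steepness: float          # k, per log10 dose unit


@dataclasses.dataclass
class TruthTable:
    """Ground truth emitted by the simulator; the acceptance oracle."""

    pairs: list[PlantedPair]
    gene_effects: pd.DataFrame     # genes x ions, sparse log-intensity effects
    drug_offtargets: pd.DataFrame  # drugs x ions
    baseline: pd.Series            # per-ion baseline intensity

    @property
    def genes(self) -> list[str]:
        return list(self.gene_effects.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.drug_offtargets.index)

    @property
    def ion_ids(self) -> list[str]:
        return list(self.gene_effects.columns)

    def pair_for_drug(self, drug: str) -> PlantedPair | None:
        for p in self.pairs:
            if p.drug == drug:
                return p
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(p) for p in self.pairs],
            columns=["gene", "drug", "mode", "potency", "inflection_log10nm", "steepness"],
        )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _sparse_effects(rng, names, ion_ids, sparsity) -> pd.DataFrame:
    """Sparse standard-normal log-effect vectors, centered on their support.

    Centering makes each perturbation a redistribution of metabolite pools
    rather than a net intensity shift: in real FIA screens the total ion
    current is dominated by thousands of unannotated ions and is nearly
    treatment-insensitive, so treatment effects must not masquerade as
    TIC outliers here.
    """
    n_ions = len(ion_ids)
    k = max(1, round(sparsity * n_ions))
    mat = np.zeros((len(names), n_ions))
    for i in range(len(names)):
        idx = rng.choice(n_ions, size=k, replace=False)
        vals = rng.normal(0.0, 1.0, size=k)
        if k > 1:
            vals = vals - vals.mean()
        mat[i, idx] = vals
    return pd.DataFrame(mat, index=list(names), columns=list(ion_ids))


def generate_truth(params: SimulationParams) -> TruthTable:
    """Draw the planted biology: effect vectors and drug-target pairings."""
    params.validate()
    rng = _rng(params.seed, 0)
    ion_ids = [f"ion{i:04d}" for i in range(params.n_ions)]
    genes = [f"G{i:03d}" for i in range(params.n_genes)]
    drugs = [f"D{i:03d}" for i in range(params.n_drugs)]
    gene_effects = _sparse_effects(rng, genes, ion_ids, params.effect_sparsity)
    drug_offtargets = _sparse_effects(rng, drugs, ion_ids, params.effect_sparsity)
    baseline = pd.Series(10 ** rng.uniform(4.0, 6.0, params.n_ions), index=ion_ids)

    lo, hi = params.inflection_range()
    sel_genes = rng.choice(params.n_genes, size=params.n_planted, replace=False)
    sel_drugs = rng.choice(params.n_drugs, size=params.n_planted, replace=False)
    pairs = []
    for gi, di in zip(sel_genes, sel_drugs):
        mode = "antagonist" if rng.random() < params.antagonist_fraction else "agonist"
        pairs.append(
            PlantedPair(
                gene=genes[gi],
                drug=drugs[di],
                mode=mode,
                potency=float(rng.uniform(0.5, 1.5)),
                inflection_log10nm=float(rng.uniform(lo, hi)),
                steepness=float(rng.uniform(1.0, 3.0)),
            )
        )
    return TruthTable(pairs, gene_effects, drug_offtargets, baseline)


def induction_level(dose: float, x0: float, k: float) -> float:
    """Logistic activation L(d) in [0, 1]; L(0) is defined as exactly 0."""
    if dose <= 0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-k * (math.log10(dose) - x0)))


def oe_shift(truth: TruthTable, params: SimulationParams, gene: str, dose: float) -> np.ndarray:
    """Log-intensity shift of gene overexpression at the given inducer dose."""
    pair = next((p for p in truth.pairs if p.gene == gene), None)
    if pair is not None:
        x0, k = pair.inflection_log10nm, pair.steepness
    else:
        # non-planted genes still respond to the inducer; stable per (seed, gene)
        tag = zlib.crc32(gene.encode()) % (2**31)
        g_rng = np.random.default_rng([int(params.seed) % (2**31), 7, tag])
        lo, hi = params.inflection_range()
        x0, k = g_rng.uniform(lo, hi), g_rng.uniform(1.0, 3.0)
    level = induction_level(dose, x0, k)
    gain = params.oe_gain * level - params.loss_gain * (1.0 - level)
    return truth.gene_effects.loc[gene].to_numpy() * gain


def _timepoint_scale(timepoint: float, timepoints: Sequence[float]) -> float:
    # later sampling gives the induced program longer to act
    tmax = max(timepoints)
    return 0.8 + 0.2 * (timepoint / tmax) if tmax > 0 else 1.0


def _layout_plates(conditions: list[dict], params: SimulationParams, control: dict, rng):
    """Assign condition wells to plates, add control wells, shuffle injection order."""
    capacity = params.plate_size - params.controls_per_plate
    rows = []
    plate_no = 0
    for start in range(0, len(conditions), capacity):
        plate_no += 1
        plate_id = f"P{plate_no:03d}"
        wells = [dict(c) for c in conditions[start : start + capacity]]
        for c in range(params.controls_per_plate):
            ctrl = dict(control)
            ctrl["replicate"] = c + 1
            wells.append(ctrl)
        order = rng.permutation(len(wells))
        for inj, widx in enumerate(order):
            w = wells[widx]
            w["plate_id"] = plate_id
            w["batch_id"] = plate_id
            w["injection_index"] = inj
            rows.append(w)
    return rows


def _measure(rows: list[dict], shifts: np.ndarray, truth: TruthTable,
             params: SimulationParams, rng) -> ScreenTable:
    """Apply artifact layers and noise; assemble the ScreenTable."""
    n = len(rows)
    n_ions = len(truth.ion_ids)
    base = truth.baseline.to_numpy()
    log_x = np.log(base)[None, :] + shifts

    # biomass effect: intensity scales as od ** e_i
    od = rng.normal(1.0, 0.1, size=n)
    od = np.where(od > 0.5, od, 1.0)
    if params.od_effect_scale > 0:
        expo = rng.normal(params.od_effect_scale, params.od_effect_scale / 4, size=n_ions)
        log_x = log_x + np.log(od)[:, None] * expo[None, :]

    # smooth per-batch injection drift: low-frequency sinusoid plus linear
    batches = pd.Series([r["batch_id"] for r in rows])
    inj = np.array([r["injection_index"] for r in rows], dtype=float)
    drift = np.zeros(n)
    if params.drift_amplitude > 0:
        for b in batches.unique():
            m = (batches == b).to_numpy()
            span = max(inj[m].max(), 1.0)
            phase = rng.uniform(0, 2 * np.pi)
            slope = rng.uniform(-1.0, 1.0)
            t = inj[m] / span
            drift[m] = params.drift_amplitude * (
                0.6 * np.sin(2 * np.pi * t + phase) + 0.4 * slope * (2 * t - 1)
            )
    log_x = log_x + np.log1p(drift)[:, None]

    if params.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + params.noise_cv**2))
        log_x = log_x + rng.normal(-sigma**2 / 2, sigma, size=(n, n_ions))

    intensities = np.exp(log_x)
    sample_ids = [f"{r['treatment_class'][:2]}{i:05d}" for i, r in enumerate(rows)]
    meta = pd.DataFrame(rows, index=sample_ids)
    meta["od600"] = od
    meta = meta[list(META_COLUMNS)]
    intens = pd.DataFrame(intensities, index=sample_ids, columns=truth.ion_ids)
    return ScreenTable(intens, meta)


def simulate_oe_screen(
    truth: TruthTable,
    params: SimulationParams,
    doses: Sequence[float] | None = None,
    timepoints: Sequence[float] | None = None,
) -> ScreenTable:
    """Inducible-overexpression screen over a dose series, with paired
    estradiol-treated wild-type control wells on every plate.

    ``doses``/``timepoints`` default to ``params`` but may be restricted,
    e.g. to ``[0, max]`` for a single-concentration experiment.
    """
    params.validate()
    doses = list(params.doses if doses is None else doses)
    timepoints = list(params.timepoints if timepoints is None else timepoints)
    rng = _rng(params.seed, 1)
    conditions = []
    for gene in truth.genes:
        for t in timepoints:
            for d in doses:
                for rep in range(1, params.replicates + 1):
                    conditions.append(
                        dict(
                            treatment_class="overexpression",
                            treatment_id=gene,
                            dose=float(d),
                            timepoint=float(t),
                            genotype=gene,
                            replicate=rep,
                        )
                    )
    control = dict(
        treatment_class="wt_control",
        treatment_id="WT",
        dose=0.0,
        timepoint=float(timepoints[0]),
        genotype="WT",
        replicate=1,
    )
    rows = _layout_plates(conditions, params, control, rng)
    tscale = {t: _timepoint_scale(t, timepoints) for t in timepoints}
    shifts = np.zeros((len(rows), len(truth.ion_ids)))
    shift_cache: dict[tuple, np.ndarray] = {}
    for i, r in enumerate(rows):
        if r["treatment_class"] != "overexpression":
            continue
        key = (r["treatment_id"], r["dose"], r["timepoint"])
        if key not in shift_cache:
            shift_cache[key] = (
                oe_shift(truth, params, r["treatment_id"], r["dose"])
                * tscale[r["timepoint"]]
            )
        shifts[i] = shift_cache[key]
    return _measure(rows, shifts, truth, params, rng)


def drug_shift(truth: TruthTable, drug: str, knockout: str | None = None) -> np.ndarray:
    """Log-intensity shift of a drug treatment.

    ``knockout`` names a deleted gene: a drug whose planted target is absent
    acts through its off-target vector only.
    """
    shift = truth.drug_offtargets.loc[drug].to_numpy().copy()
    pair = truth.pair_for_drug(drug)
    if pair is not None and pair.gene != knockout:
        sign = 1.0 if pair.mode == "agonist" else -1.0
        shift = shift + sign * pair.potency * truth.gene_effects.loc[pair.gene].to_numpy()
    return shift


def simulate_drug_screen(truth: TruthTable, params: SimulationParams) -> ScreenTable:
    """Chemical-library screen at a fixed drug concentration with DMSO
    vehicle wells on every plate."""
    params.validate()
    rng = _rng(params.seed, 2)
    conditions = []
    for drug in truth.drugs:
        for rep in range(1, params.replicates + 1):
            conditions.append(
                dict(
                    treatment_class="drug",
                    treatment_id=drug,
                    dose=params.drug_dose_nm,
                    timepoint=0.5,
                    genotype="WT",
                    replicate=rep,
                )
            )
    control = dict(
        treatment_class="vehicle_control",
        treatment_id="DMSO",
        dose=0.0,
        timepoint=0.5,
        genotype="WT",
        replicate=1,
    )
    rows = _layout_plates(conditions, params, control, rng)
    shifts = np.zeros((len(rows), len(truth.ion_ids)))
    cache: dict[str, np.ndarray] = {}
    for i, r in enumerate(rows):
        if r["treatment_class"] != "drug":
            continue
        d = r["treatment_id"]
        if d not in cache:
            cache[d] = drug_shift(truth, d)
        shifts[i] = cache[d]
    return _measure(rows, shifts, truth, params, rng)


def simulate_genotype_screen(
    truth: TruthTable,
    params: SimulationParams,
    pairs: Sequence[PlantedPair] | None = None,
    replicates: int = 4,
) -> ScreenTable:
    """Chemical-genetic follow-up: wild type and target-deletion mutants
    treated with hit drugs or vehicle.

    For each planted pair the mutant (genotype ``del_<gene>``) lacks the
    drug's target, so its drug response is the off-target vector only; the
    deletion background itself carries the loss-of-function shift.
    """
    params.validate()
    if pairs is None:
        pairs = truth.pairs
    rng = _rng(params.seed, 3)
    rows = []
    shifts = []
    plate_no = 0
    for pair in pairs:
        plate_no += 1
        plate_id = f"CG{plate_no:03d}"
        wells: list[tuple[dict, np.ndarray]] = []
        loss = -params.loss_gain * truth.gene_effects.loc[pair.gene].to_numpy()
        for genotype, background, knockout in (
            ("WT", np.zeros(len(truth.ion_ids)), None),
            (f"del_{pair.gene}", loss, pair.gene),
        ):
            for rep in range(1, replicates + 1):
                wells.append(
                    (
                        dict(
                            treatment_class="drug",
                            treatment_id=pair.drug,
                            dose=params.drug_dose_nm,
                            timepoint=0.5,
                            genotype=genotype,
                            replicate=rep,
                        ),
                        background + drug_shift(truth, pair.drug, knockout=knockout),
                    )
                )
                wells.append(
                    (
                        dict(
                            treatment_class="vehicle_control",
                            treatment_id="DMSO",
                            dose=0.0,
                            timepoint=0.5,
                            genotype=genotype,
                            replicate=rep,
                        ),
                        background.copy(),
                    )
                )
        order = rng.permutation(len(wells))
        for inj, widx in enumerate(order):
            w, s = wells[widx]
            w["plate_id"] = plate_id
            w["batch_id"] = plate_id
            w["injection_index"] = inj
            rows.append(w)
            shifts.append(s)
    return _measure(rows, np.array(shifts), truth, params, rng)


# ---------------------------------------------------------------------------
# molecules and GO annotations
# ---------------------------------------------------------------------------

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
_ELEMENTS = ("C", "N", "O", "S")
_ELEMENT_P = (0.70, 0.12, 0.13, 0.05)


def _random_molecule(rng, name: str) -> MoleculeGraph:
    n_atoms = int(rng.integers(6, 17))
    atoms = [str(rng.choice(_ELEMENTS, p=_ELEMENT_P)) for _ in range(n_atoms)]
    free = [_VALENCE[a] for a in atoms]
    bonds: list[tuple[int, int, object]] = []
    for i in range(1, n_atoms):
        candidates = [j for j in range(i) if free[j] >= 1]
        if not candidates:
            atoms[i] = "C"  # should not happen; keep graph connected
            candidates = [0]
        j = int(rng.choice(candidates))
        order = 1
        if free[j] >= 2 and free[i] >= 2 and rng.random() < 0.15:
            order = 2
        bonds.append((j, i, order))
        free[i] -= order
        free[j] -= order
    # occasional single ring closure between distant atoms with spare valence
    if rng.random() < 0.3:
        spare = [i for i in range(n_atoms) if free[i] >= 1]
        rng.shuffle(spare)
        bonded = {frozenset((a, b)) for a, b, _ in bonds}
        for a in spare:
            partners = [b for b in spare if abs(b - a) >= 3 and frozenset((a, b)) not in bonded]
            if partners:
                b = int(partners[0])
                bonds.append((min(a, b), max(a, b), 1))
                break
    return MoleculeGraph(name=name, atoms=atoms, bonds=bonds)


def _family_molecule(rng, name: str) -> MoleculeGraph:
    # shared scaffold: an aromatic six-ring; decorations vary per member
    atoms = ["C"] * 6
    bonds: list[tuple[int, int, object]] = [(i, (i + 1) % 6, "ar") for i in range(6)]
    free = [1] * 6  # one substituent slot per aromatic carbon
    n_dec = int(rng.integers(2, 7))
    attach_points = list(range(6))
    for _ in range(n_dec):
        sites = [i for i in attach_points if free[i] >= 1]
        if not sites:
            break
        site = int(rng.choice(sites))
        el = str(rng.choice(_ELEMENTS, p=_ELEMENT_P))
        atoms.append(el)
        new = len(atoms) - 1
        bonds.append((site, new, 1))
        free[site] -= 1
        free.append(_VALENCE[el] - 1)
        attach_points.append(new)
    return MoleculeGraph(name=name, atoms=atoms, bonds=bonds)


def simulate_molecules(
    n: int, planted_family_size: int = 0, seed: int = 0
) -> list[MoleculeGraph]:
    """Random small molecules plus a planted family sharing a 6-atom scaffold.

    Family members come first (named ``F...``); the remainder are random
    plausible-valence graphs of 6-16 heavy atoms (named ``R...``).
    """
    if planted_family_size > n:
        raise ValueError("planted_family_size exceeds n")
    rng = _rng(seed, 4)
    mols = [_family_molecule(rng, f"F{i:03d}") for i in range(planted_family_size)]
    mols += [_random_molecule(rng, f"R{i:03d}") for i in range(n - planted_family_size)]
    return mols


def simulate_go_annotations(
    genes: Sequence[str],
    n_terms: int,
    coherent_clusters: Mapping[str, int] | None = None,
    seed: int = 0,
    coherence: float = 0.8,
) -> pd.DataFrame:
    """Flat gene -> GO-term annotation table.

    Background annotation rates per term are Uniform(0.02, 0.2).  Genes in
    designated coherent clusters are additionally annotated to a
    cluster-specific term with probability ``coherence``.
    """
    if not genes:
        raise ValueError("genes must be nonempty")
    rng = _rng(seed, 5)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    rates = rng.uniform(0.02, 0.2, size=n_terms)
    records = []
    for g in genes:
        hits = rng.random(n_terms) < rates
        for t, h in zip(terms, hits):
            if h:
                records.append((g, t))
    if coherent_clusters:
        for g in genes:
            cid = coherent_clusters.get(g)
            if cid is not None and rng.random() < coherence:
                records.append((g, f"GO:C{int(cid):04d}"))
    return pd.DataFrame(records, columns=["gene", "term"]).drop_duplicates(
        ignore_index=True
    )
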