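"""Seeded synthetic worlds with planted interaction structure.

These generators emulate every input the pipeline consumes — random binary
fingerprints, random amino-acid sequences, labeled interaction triples, a
multi-source bioactivity table, and a scaffold-hopping benchmark — with a
*planted* bilinear scorer so that recovery is checkable: labels come from
``sign(psi_M(m)^T W* psi_P(p) + b*)`` in a known feature space, flipped
with a configurable noise probability.

Everything is a pure function of its parameters and seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .curation import BIOACTIVITY_COLUMNS
from .evaluation import HopCase
from .exceptions import GenerationError
from .features import fit_feature_map
from .io import AMINO_ACIDS, InteractionSet, MoleculeRecord, ProteinRecord, Registry
from .kernels import LAKernelParams, LocalAlignmentKernel, TanimotoKernel


@dataclasses.dataclass
class PlantedWorld:
    """Entities plus the planted bilinear ground truth."""

    molecules: Registry
    proteins: Registry
    fingerprints: np.ndarray  # n_M x n_bits
    sequences: list[str]
    W_star: np.ndarray
    b_star: float
    pair_scores: np.ndarray  # n_M x n_P raw scores, bias excluded
    noise: float
    seed: int
    feature_source: str

    @property
    def n_M(self) -> int:
        return self.fingerprints.shape[0]

    @property
    def n_P(self) -> int:
        return len(self.sequences)

    def true_score(self, i: int, j: int) -> float:
        """Planted margin of pair (i, j) — the oracle scorer."""
        return float(self.pair_scores[i, j] + self.b_star)

    def true_label(self, i: int, j: int) -> int:
        return 1 if self.true_score(i, j) >= 0 else -1

    @property
    def prevalence(self) -> float:
        return float((self.pair_scores + self.b_star >= 0).mean())


def _aa_composition(seq: str) -> np.ndarray:
    counts = np.array([seq.count(a) for a in AMINO_ACIDS], dtype=float)
    return counts / len(seq)


def make_world(
    n_M: int = 200,
    n_P: int = 30,
    n_bits: int = 1024,
    p_bit: float = 0.05,
    n_scaffolds: int = 20,
    mol_mutation: float = 0.15,
    seq_len: tuple[int, int] = (30, 60),
    n_families: int = 6,
    prot_mutation: float = 0.15,
    mol_feature_dim: int = 16,
    prot_feature_dim: int = 16,
    mol_fine_dim: int = 32,
    fine_fraction: float = 0.15,
    rank: int = 4,
    noise: float = 0.05,
    target_prevalence: float = 0.5,
    feature_source: str = "pipeline",
    la_params: LAKernelParams | None = None,
    seed: int = 0,
) -> PlantedWorld:
    """Build a planted world.

    Entities are *clustered*, mimicking the structure of real chemical and
    protein space: molecules derive from ``n_scaffolds`` random scaffold
    fingerprints (Bernoulli(p_bit) bits) by per-bit mutation at rate
    ``mol_mutation`` (off-bit activations are rescaled to preserve density),
    and proteins derive from ``n_families`` random base sequences by per-residue
    substitution at rate ``prot_mutation``.  Without this similarity
    structure the kernel Grams are near-identity and no method could
    generalize across pairs.

    ``feature_source`` selects the space in which the planted scorer acts:
    ``"pipeline"`` (default) uses the package's own exact kernel feature
    maps, making the labels realizable by the model under test; ``"raw"``
    plants the scorer on raw fingerprints and amino-acid compositions,
    a deliberately misspecified, harder task.

    The bias ``b*`` is tuned so the fraction of positive pairs over the
    full n_M x n_P grid hits ``target_prevalence``; a resulting prevalence
    outside [0.3, 0.7] raises :class:`GenerationError`.
    """
    rng = np.random.default_rng(seed)
    scaffolds = (rng.random((n_scaffolds, n_bits)) < p_bit).astype(np.uint8)
    assign = rng.integers(n_scaffolds, size=n_M)
    # mutate: on-bits drop at rate mu; off-bits switch on at the rate that
    # keeps the expected popcount unchanged
    mu = mol_mutation
    on_rate = mu * p_bit / (1.0 - p_bit)
    base = scaffolds[assign]
    u = rng.random((n_M, n_bits))
    fingerprints = np.where(base == 1, (u >= mu), (u < on_rate)).astype(np.uint8)
    # guarantee no empty fingerprint (Tanimoto is undefined there)
    for i in np.flatnonzero(fingerprints.sum(axis=1) == 0):
        fingerprints[i, rng.integers(n_bits)] = 1

    lo, hi = seq_len
    alphabet = np.array(list(AMINO_ACIDS))
    family_seqs = [
        rng.choice(alphabet, size=int(rng.integers(lo, hi + 1)))
        for _ in range(n_families)
    ]
    fam_assign = rng.integers(n_families, size=n_P)
    sequences = []
    for j in range(n_P):
        s = family_seqs[fam_assign[j]].copy()
        mut = rng.random(len(s)) < prot_mutation
        s[mut] = rng.choice(alphabet, size=int(mut.sum()))
        sequences.append("".join(s))

    molecules = Registry(
        MoleculeRecord(mol_id=f"M{i:05d}", fingerprint=fingerprints[i])
        for i in range(n_M)
    )
    proteins = Registry(
        ProteinRecord(prot_id=f"P{j:04d}", sequence=sequences[j]) for j in range(n_P)
    )

    if feature_source == "pipeline":
        d_coarse = min(mol_feature_dim, n_M)
        d_total = min(mol_feature_dim + mol_fine_dim, n_M)
        mol_map = fit_feature_map(
            list(fingerprints), TanimotoKernel(),
            dim=d_total,
            seed=int(rng.integers(2**31)),
        )
        prot_map = fit_feature_map(
            sequences,
            LocalAlignmentKernel(la_params or LAKernelParams()),
            dim=min(prot_feature_dim, n_P),
            seed=int(rng.integers(2**31)),
        )
        M = mol_map.transform_batch(list(fingerprints))
        P = prot_map.transform_batch(sequences)
    elif feature_source == "raw":
        M = fingerprints.astype(float)
        M = (M - M.mean(axis=0)) / (M.std(axis=0) + 1e-9)
        P = np.stack([_aa_composition(s) for s in sequences])
        P = (P - P.mean(axis=0)) / (P.std(axis=0) + 1e-9)
    else:
        raise ValueError("feature_source must be 'pipeline' or 'raw'")

    d_M, d_P = M.shape[1], P.shape[1]
    if feature_source == "pipeline" and d_M > min(mol_feature_dim, n_M):
        # coarse (scaffold-level) signal in the leading eigendirections plus
        # a minority within-scaffold component in the next directions, scaled
        # so the fine part carries `fine_fraction` of the score variance
        d_c = min(mol_feature_dim, n_M)
        Uc = rng.standard_normal((d_c, rank))
        Vc = rng.standard_normal((d_P, rank))
        Wc = (Uc @ Vc.T) / np.sqrt(rank)
        # fine part is rank one against the leading protein direction: one
        # latent scalar per molecule, learnable from that molecule's own
        # training pairs but unpredictable for held-out molecules
        Uf = rng.standard_normal((d_M - d_c, 1))
        Vf = np.zeros((d_P, 1))
        Vf[0, 0] = 1.0
        Wf = Uf @ Vf.T
        s_c = M[:, :d_c] @ Wc @ P.T
        s_f = M[:, d_c:] @ Wf @ P.T
        sd_f = s_f.std()
        if fine_fraction > 0 and sd_f > 0:
            beta = math.sqrt(fine_fraction / (1.0 - fine_fraction)) * s_c.std() / sd_f
        else:
            beta = 0.0
        W_star = np.vstack([Wc, beta * Wf])
        scores = s_c + beta * s_f
    else:
        U = rng.standard_normal((d_M, rank))
        V = rng.standard_normal((d_P, rank))
        W_star = (U @ V.T) / np.sqrt(rank)
        scores = M @ W_star @ P.T
    b_star = -float(np.quantile(scores, 1.0 - target_prevalence))
    prevalence = float((scores + b_star >= 0).mean())
    if not 0.3 <= prevalence <= 0.7:
        raise GenerationError(
            f"achieved prevalence {prevalence:.3f} outside [0.3, 0.7]; "
            f"target was {target_prevalence}"
        )
    return PlantedWorld(
        molecules=molecules,
        proteins=proteins,
        fingerprints=fingerprints,
        sequences=sequences,
        W_star=W_star,
        b_star=b_star,
        pair_scores=scores,
        noise=noise,
        seed=seed,
        feature_source=feature_source,
    )


def generate_interactions(
    world: PlantedWorld, n_Z: int = 2000, seed: int = 0
) -> InteractionSet:
    """Sample labeled pairs from the planted world.

    Pairs are drawn without replacement over the n_M x n_P grid; labels are
    the planted signs, each flipped independently with probability
    ``world.noise``.
    """
    total = world.n_M * world.n_P
    if n_Z > total:
        raise GenerationError(f"n_Z={n_Z} exceeds the {total} available pairs")
    rng = np.random.default_rng([world.seed, seed, 7919])
    flat = rng.choice(total, size=n_Z, replace=False)
    mol_idx = flat // world.n_P
    prot_idx = flat % world.n_P
    margins = world.pair_scores[mol_idx, prot_idx] + world.b_star
    labels = np.where(margins >= 0, 1, -1)
    flips = rng.random(n_Z) < world.noise
    labels = np.where(flips, -labels, labels)
    return InteractionSet(
        world.molecules, world.proteins,
        mol_idx.astype(np.int64), prot_idx.astype(np.int64), labels.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# bioactivity table with bookkeeping


@dataclasses.dataclass
class BioactivityBookkeeping:
    """What the curation filters *should* find, computed at generation time."""

    n_records_total: int
    mismatch_mol_ids: list[str]
    disagreement_pairs: list[tuple[str, str]]
    n_records_after_structure: int
    n_pairs_measured: int
    n_pairs_concordant: int
    n_positive: int
    n_negative: int
    n_nonconclusive: int


def generate_bioactivities(
    world: PlantedWorld,
    n_records: int = 100,
    multi_source_rate: float = 0.2,
    structure_mismatch_rate: float = 0.1,
    disagreement_rate: float = 0.1,
    seed: int = 0,
    value_override: float | None = None,
) -> tuple[pd.DataFrame, BioactivityBookkeeping]:
    """Multi-source bioactivity table exercising every curation filter.

    ``n_records`` base records are drawn over distinct (molecule, protein)
    pairs with log-uniform values in [1e-10, 1e-2] M.  A
    ``multi_source_rate`` fraction gains a duplicate from a second source;
    among the duplicated records, ``structure_mismatch_rate * n_records``
    carry a mismatched SMILES (their molecules must be dropped by the
    structure filter) and ``disagreement_rate * n_records`` carry a value
    on the far side of the conclusive window (a >1-log-unit disagreement
    that must make the pair nonconclusive); remaining duplicates agree
    exactly.  Returns the shuffled table plus bookkeeping of the counts
    each curation stage must reproduce.
    """
    for r in (multi_source_rate, structure_mismatch_rate, disagreement_rate):
        if not 0.0 <= r <= 1.0:
            raise GenerationError("rates must lie in [0, 1]")
    n_multi = round(multi_source_rate * n_records)
    n_mm = round(structure_mismatch_rate * n_records)
    n_dis = round(disagreement_rate * n_records)
    if n_mm + n_dis > n_multi:
        raise GenerationError(
            "structure_mismatch_rate + disagreement_rate cannot exceed "
            "multi_source_rate"
        )
    if n_records > world.n_M:
        raise GenerationError("need n_records <= n_M for distinct base molecules")

    rng = np.random.default_rng([world.seed, seed, 104729])
    mol_ids = world.molecules.ids
    prot_ids = world.proteins.ids
    base_mols = rng.choice(world.n_M, size=n_records, replace=False)

    rows = []
    values = 10.0 ** rng.uniform(-10, -2, size=n_records)
    if value_override is not None:
        values = np.full(n_records, value_override)
    measure_types = rng.choice(["Kd", "Ki", "IC50"], size=n_records)
    for k in range(n_records):
        i = int(base_mols[k])
        j = int(rng.integers(world.n_P))
        rows.append(
            {
                "source_db": "SRC_A",
                "mol_id": mol_ids[i],
                "smiles": f"FP:{mol_ids[i]}",
                "prot_id": prot_ids[j],
                "organism": "Homo sapiens",
                "measure_type": str(measure_types[k]),
                "value_molar": float(values[k]),
                "mol_weight": float(rng.uniform(100.0, 900.0)),
            }
        )

    dup_targets = rng.choice(n_records, size=n_multi, replace=False)
    mismatch_ids, disagreement_pairs = [], []
    for t, k in enumerate(dup_targets):
        dup = dict(rows[int(k)])
        dup["source_db"] = "SRC_B"
        if t < n_mm:
            dup["smiles"] = dup["smiles"] + "_ALT"
            mismatch_ids.append(dup["mol_id"])
        elif t < n_mm + n_dis:
            # put the duplicate on the far side of the conclusive window
            base_v = rows[int(k)]["value_molar"]
            dup["value_molar"] = 1e-3 if base_v < 1e-7 else 1e-9
            disagreement_pairs.append((dup["mol_id"], dup["prot_id"]))
        rows.append(dup)

    # bookkeeping, derived from construction (not by running the filters)
    mismatch_set = set(mismatch_ids)
    n_total = len(rows)
    n_after_structure = sum(r["mol_id"] not in mismatch_set for r in rows)
    surviving_base = [k for k in range(n_records) if rows[k]["mol_id"] not in mismatch_set]
    n_pairs = len(surviving_base)  # base pairs are distinct by construction
    n_concordant = n_pairs - len(disagreement_pairs)
    n_pos = n_neg = n_non = 0
    dis_pair_set = set(disagreement_pairs)
    for k in surviving_base:
        if (rows[k]["mol_id"], rows[k]["prot_id"]) in dis_pair_set:
            n_non += 1  # mixed-side values under a >1-log disagreement
        else:
            v = rows[k]["value_molar"]
            if v < 1e-7:
                n_pos += 1
            elif v > 1e-4:
                n_neg += 1
            else:
                n_non += 1

    df = pd.DataFrame(rows, columns=BIOACTIVITY_COLUMNS + ["mol_weight"])
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    book = BioactivityBookkeeping(
        n_records_total=n_total,
        mismatch_mol_ids=sorted(mismatch_set),
        disagreement_pairs=sorted(disagreement_pairs),
        n_records_after_structure=n_after_structure,
        n_pairs_measured=n_pairs,
        n_pairs_concordant=n_concordant,
        n_positive=n_pos,
        n_negative=n_neg,
        n_nonconclusive=n_non,
    )
    return df, book


# ---------------------------------------------------------------------------
# scaffold-hopping benchmark


def generate_hop_benchmark(
    world: PlantedWorld,
    n_cases: int = 20,
    n_decoys: int = 499,
    seed: int = 0,
) -> list[HopCase]:
    """Hop cases from the planted ground truth (noise-free labels).

    Each case picks a protein with at least two planted positives, uses two
    of them as the known/unknown active pair, and samples decoys from that
    protein's planted negatives.  Proteins with too few positives or
    negatives are skipped.
    """
    rng = np.random.default_rng([world.seed, seed, 15485863])
    margins = world.pair_scores + world.b_star
    cases: list[HopCase] = []
    prot_order = rng.permutation(world.n_P)
    attempt = 0
    while len(cases) < n_cases and attempt < 20 * n_cases:
        j = int(prot_order[attempt % world.n_P])
        attempt += 1
        pos = np.flatnonzero(margins[:, j] >= 0)
        neg = np.flatnonzero(margins[:, j] < 0)
        if len(pos) < 2 or len(neg) < n_decoys:
            continue
        known, unknown = rng.choice(pos, size=2, replace=False)
        decoys = rng.choice(neg, size=n_decoys, replace=False)
        cases.append(
            HopCase(
                case_id=f"case{len(cases):03d}",
                query_prot=j,
                known_active=int(known),
                unknown_active=int(unknown),
                decoys=[int(d) for d in decoys],
            )
        )
    if len(cases) < n_cases:
        raise GenerationError(
            f"only {len(cases)} of {n_cases} hop cases could be built "
            f"(need >= 2 positives and >= {n_decoys} negatives per protein)"
        )
    return cases
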