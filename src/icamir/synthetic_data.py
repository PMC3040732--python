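"""Ground-truth-annotated synthetic data generation.

Builds complete pipeline inputs — sparse super-Gaussian transcriptional
programs, design-driven mixes, planted miRNA target repression, seed-matched
sequences (miRNA mature sequences + 3'UTRs), miRNA profiles as noisy
superpositions of the program mixes, and pathway gene sets — together with a
truth manifest, so every stage can be tested without external downloads.

Programs use Laplace-distributed loads: ICA identifiability requires
non-Gaussian sources, so the generator is explicitly super-Gaussian.
All generators are bit-reproducible from ``rng_seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
    write_expression_table,
    write_fasta,
    write_gmt,
)
from .seed_targets import extract_seed, scan_utr

logger = logging.getLogger(__name__)

_DNA = np.array(list("ACGT"))
_RNA = np.array(list("ACGU"))


@dataclass
class SimulationTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    gene_ids: list
    sample_ids: list
    mirna_ids: list            # planted (effect-carrying) miRNAs
    decoy_ids: list            # miRNAs with target sites but no load effect
    C_true: np.ndarray         # programs before planting (G x T)
    C_modified: np.ndarray     # programs after planting + restandardization
    M_true: np.ndarray         # T x S mixes
    planted_targets: dict      # mirna_id -> set of gene ids
    planted_effect: dict       # (mirna_id, program) -> load shift
    program_assignment: dict   # mirna_id -> program index
    mirna_coefficients: np.ndarray  # (n_mirnas + n_decoys) x T superposition weights
    coefficient_ids: list      # row order of mirna_coefficients
    effect_map: dict           # program -> (factor, effect)
    pathway_assignments: dict = field(default_factory=dict)  # name -> info dict
    rng_seed: int = 0

    def to_json_dict(self) -> dict:
        return {
            "gene_ids": self.gene_ids,
            "sample_ids": self.sample_ids,
            "mirna_ids": self.mirna_ids,
            "decoy_ids": self.decoy_ids,
            "C_true": self.C_true.tolist(),
            "C_modified": self.C_modified.tolist(),
            "M_true": self.M_true.tolist(),
            "planted_targets": {m: sorted(g) for m, g in self.planted_targets.items()},
            "planted_effect": {f"{m}|{p}": e for (m, p), e in self.planted_effect.items()},
            "program_assignment": self.program_assignment,
            "mirna_coefficients": self.mirna_coefficients.tolist(),
            "coefficient_ids": self.coefficient_ids,
            "effect_map": {str(p): list(fe) for p, fe in self.effect_map.items()},
            "pathway_assignments": {
                name: {**info, "genes": sorted(info["genes"])}
                for name, info in self.pathway_assignments.items()
            },
            "rng_seed": self.rng_seed,
        }


# ---------------------------------------------------------------------------
# Programs and mixes
# ---------------------------------------------------------------------------

def simulate_programs(G: int, T: int, sparsity: float, rng_seed: int = 0) -> np.ndarray:
    """Sparse Laplace program loads, standardized per column to mean 0 /
    variance 1. A ``sparsity`` fraction of genes is active per program."""
    if not (0 < sparsity <= 1):
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    if T < 1 or G < T:
        raise ValueError("need G >= T >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    C = np.zeros((G, T))
    k = max(2, int(round(sparsity * G)))
    for t in range(T):
        idx = rng.choice(G, size=k, replace=False)
        C[idx, t] = rng.laplace(0.0, 1.0, size=k)
    C -= C.mean(axis=0)
    C /= C.std(axis=0)
    return C


def simulate_design_and_mixes(
    T: int,
    factors: Mapping[str, Sequence[str]],
    replicates: int,
    effect_map: Mapping[int, tuple],
    sigma_mix: float = 0.3,
    rng_seed: int = 0,
) -> tuple:
    """Build the sample design (full factor cross, ``replicates`` each) and
    the T x S mix matrix.

    A program mapped in ``effect_map`` to ``(factor, effect)`` takes the value
    ``effect`` in samples at that factor's last ("on") level, 0 elsewhere,
    plus ``N(0, sigma_mix)`` replicate noise. Unmapped programs receive
    condition-independent standard-normal mixes.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates per design cell for F-tests")
    for p, (fac, _) in effect_map.items():
        if fac not in factors:
            raise ValueError(f"program {p} mapped to unknown factor {fac!r}")
        if not (0 <= p < T):
            raise ValueError(f"program index {p} out of range for T={T}")

    names = list(factors)
    level_grids = [list(factors[f]) for f in names]
    cells = [[]]
    for levels in level_grids:
        cells = [c + [lv] for c in cells for lv in levels]

    rows = []
    for cell in cells:
        for r in range(1, replicates + 1):
            rows.append(dict(zip(names, cell), replicate=r, is_control=False))
    df = pd.DataFrame(rows)
    df.insert(0, "sample_id", [f"s{i + 1:02d}" for i in range(len(df))])
    design = SampleDesign(df, factor_names=names)

    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    S = len(df)
    M = np.zeros((T, S))
    for t in range(T):
        if t in effect_map:
            fac, eff = effect_map[t]
            on_level = list(factors[fac])[-1]
            on = (df[fac] == on_level).to_numpy()
            M[t] = eff * on + rng.normal(0.0, sigma_mix, size=S)
        else:
            M[t] = rng.standard_normal(S)
    return design, M


# ---------------------------------------------------------------------------
# Planting miRNA regulation
# ---------------------------------------------------------------------------

def plant_mirna_regulation(
    C_true: np.ndarray,
    mirna_ids: Sequence[str],
    program_assignment: Mapping[str, int],
    target_fraction: float,
    effect: float,
    rng_seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> tuple:
    """Assign each miRNA a random target gene set and shift those genes'
    loads in the miRNA's program by ``effect`` (negative = repression).

    Modified columns are re-standardized. Overlapping plants on one gene sum
    (logged). Returns ``(C_modified, planted_targets, planted_effect)``.
    """
    G, T = C_true.shape
    n_targets = int(round(target_fraction * G))
    if n_targets < 20:
        raise ValueError(f"target_fraction {target_fraction} yields {n_targets} < 20 targets per miRNA")
    gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i + 1:04d}" for i in range(G)]
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    delta = np.zeros_like(C_true)
    planted_targets: dict = {}
    planted_effect: dict = {}
    hit_count = np.zeros((G, T), dtype=int)
    for m in mirna_ids:
        prog = program_assignment[m]
        idx = rng.choice(G, size=n_targets, replace=False)
        planted_targets[m] = {gene_ids[i] for i in idx}
        delta[idx, prog] += effect
        hit_count[idx, prog] += 1
        planted_effect[(m, prog)] = effect
    n_overlap = int((hit_count > 1).sum())
    if n_overlap:
        logger.info("%d gene/program cells carry summed overlapping plants", n_overlap)
    C_mod = C_true + delta
    touched = sorted({program_assignment[m] for m in mirna_ids})
    for t in touched:
        C_mod[:, t] -= C_mod[:, t].mean()
        C_mod[:, t] /= C_mod[:, t].std()
    return C_mod, planted_targets, planted_effect


# ---------------------------------------------------------------------------
# Sequence emission
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, alphabet: np.ndarray) -> str:
    return "".join(rng.choice(alphabet, size=length))


def _scrub(seq: str, patterns: Sequence[str], rng: np.random.Generator,
           max_rounds: int = 2000) -> str:
    """Mutate bases until the sequence contains no occurrence of any pattern."""
    s = list(seq)
    for _ in range(max_rounds):
        text = "".join(s)
        hit = None
        for pat in patterns:
            i = text.find(pat)
            if i != -1:
                hit = (i, len(pat))
                break
        if hit is None:
            return text
        pos = hit[0] + int(rng.integers(hit[1]))
        choices = [b for b in "ACGT" if b != s[pos]]
        s[pos] = choices[int(rng.integers(3))]
    raise RuntimeError("could not scrub seed matches from a random sequence")


def emit_sequences(
    planted_targets: Mapping[str, set],
    gene_ids: Sequence[str],
    utr_length: int = 300,
    rng_seed: int = 0,
    seed_start: int = 2,
    seed_len: int = 6,
    mature_length: int = 22,
    contaminate: float = 0.0,
) -> tuple:
    """Emit mature miRNA sequences and 3'UTRs realizing the planted target
    map exactly.

    miRNAs get random ``mature_length``-mers with pairwise-distinct seeds
    (collisions regenerated, logged). Target UTRs contain >= 1 inserted match
    site per targeting miRNA; non-target UTRs are scrubbed to contain none.
    ``contaminate > 0`` deliberately adds a random site to that fraction of
    non-target UTRs (robustness testing; breaks round-trip exactness).
    """
    if utr_length < 50:
        raise ValueError("utr_length must be >= 50")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    mirna_ids = list(planted_targets)

    mirna_seqs: dict = {}
    patterns: dict = {}
    seen_seeds: set = set()
    for m in mirna_ids:
        for _ in range(1000):
            seq = _random_seq(rng, mature_length, _RNA)
            seed_rna, match_dna = extract_seed(seq, seed_start, seed_len)
            if seed_rna not in seen_seeds:
                seen_seeds.add(seed_rna)
                mirna_seqs[m] = seq
                patterns[m] = match_dna
                break
            logger.info("seed collision for %s; regenerating", m)
        else:
            raise RuntimeError("could not generate a distinct seed")

    targeting: dict = {g: [] for g in gene_ids}
    for m, genes in planted_targets.items():
        for g in genes:
            targeting[g].append(m)

    all_patterns = [patterns[m] for m in mirna_ids]
    utrs: dict = {}
    for g in gene_ids:
        hitters = targeting[g]
        for _ in range(100):
            base = _scrub(_random_seq(rng, utr_length, _DNA), all_patterns, rng)
            if not hitters:
                utrs[g] = base
                break
            s = list(base)
            used: list = []
            ok = True
            for m in hitters:
                for _ in range(200):
                    pos = int(rng.integers(utr_length - seed_len + 1))
                    if all(abs(pos - u) >= seed_len for u in used):
                        used.append(pos)
                        s[pos : pos + seed_len] = patterns[m]
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            cand = "".join(s)
            if all(scan_utr(cand, patterns[m]) >= 1 for m in hitters) and all(
                scan_utr(cand, patterns[m]) == 0 for m in mirna_ids if m not in hitters
            ):
                utrs[g] = cand
                break
        else:
            raise RuntimeError(f"could not emit a valid UTR for gene {g}")

    if contaminate > 0:
        non_targets = [g for g in gene_ids if not targeting[g]]
        n_contam = int(round(contaminate * len(non_targets)))
        for g in rng.choice(non_targets, size=n_contam, replace=False):
            m = mirna_ids[int(rng.integers(len(mirna_ids)))]
            pos = int(rng.integers(utr_length - seed_len + 1))
            s = list(utrs[g])
            s[pos : pos + seed_len] = patterns[m]
            utrs[g] = "".join(s)
        logger.info("contaminated %d non-target UTRs with background sites", n_contam)

    return mirna_seqs, utrs


# ---------------------------------------------------------------------------
# Expression emission
# ---------------------------------------------------------------------------

def emit_expression(
    C_modified: np.ndarray,
    M_true: np.ndarray,
    noise_sd: float,
    mirna_coefficients: np.ndarray,
    mirna_noise_sd: float,
    rng_seed: int = 0,
    gene_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
    mirna_ids: Sequence[str] | None = None,
) -> tuple:
    """mRNA matrix = C_modified @ M_true + noise; miRNA matrix =
    coefficients @ M_true + noise. Returns two ``ExpressionMatrix``."""
    C = np.asarray(C_modified, float)
    M = np.asarray(M_true, float)
    coeffs = np.atleast_2d(np.asarray(mirna_coefficients, float))
    if C.shape[1] != M.shape[0] or coeffs.shape[1] != M.shape[0]:
        raise ValueError("dimension mismatch between programs, mixes and coefficients")
    G, S = C.shape[0], M.shape[1]
    gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i + 1:04d}" for i in range(G)]
    sample_ids = list(sample_ids) if sample_ids is not None else [f"s{j + 1:02d}" for j in range(S)]
    mirna_ids = list(mirna_ids) if mirna_ids is not None else [f"mir{i + 1}" for i in range(coeffs.shape[0])]
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    E = C @ M + (rng.normal(0.0, noise_sd, size=(G, S)) if noise_sd > 0 else 0.0)
    R = coeffs @ M + (rng.normal(0.0, mirna_noise_sd, size=(coeffs.shape[0], S)) if mirna_noise_sd > 0 else 0.0)
    return (
        ExpressionMatrix(gene_ids, sample_ids, E),
        ExpressionMatrix(mirna_ids, sample_ids, R),
    )


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    design: SampleDesign
    mirna_seqs: dict
    utrs: dict
    genesets: GeneSetCollection
    truth: SimulationTruth


def generate_bundle(
    G: int = 2000,
    T: int = 5,
    sparsity: float = 0.15,
    factors: Mapping[str, Sequence[str]] | None = None,
    replicates: int = 3,
    effect_map: Mapping[int, tuple] | None = None,
    sigma_mix: float = 0.3,
    n_mirnas: int = 8,
    n_decoys: int = 4,
    target_fraction: float = 0.05,
    effect: float = -1.5,
    noise_sd: float = 0.1,
    mirna_noise_sd: float = 0.05,
    mirna_amplitude: float = 3.0,
    utr_length: int = 300,
    pathway_size: int = 30,
    n_null_pathways: int = 3,
    emit_seqs: bool = True,
    contaminate: float = 0.0,
    rng_seed: int = 0,
) -> SyntheticBundle:
    """Generate a complete, internally consistent synthetic input bundle.

    The default fixture mirrors the assumed data shape qualitatively: 5
    programs of which 3 are tied to binary design factors, a 2x2x2 factor
    design with 3 replicates (24 samples), ~2000 genes, 8 effect-carrying
    miRNAs plus decoys, repression effect -1.5 on 5% of genes per miRNA.
    """
    if factors is None:
        factors = {"pdx1": ["off", "on"], "il1b": ["no", "yes"], "time": ["2h", "24h"]}
    if effect_map is None:
        n_mapped = min(3, T)
        fac_names = list(factors)
        effect_map = {t: (fac_names[t % len(fac_names)], 5.0) for t in range(n_mapped)}

    ss = np.random.SeedSequence(rng_seed)
    s_prog, s_mix, s_plant, s_seq, s_expr, s_misc = [
        int(c.generate_state(1)[0]) for c in ss.spawn(6)
    ]
    rng = np.random.default_rng(np.random.SeedSequence(s_misc))

    gene_ids = [f"g{i + 1:04d}" for i in range(G)]
    mirna_ids = [f"mir-{100 + i}" for i in range(n_mirnas)]
    decoy_ids = [f"decoy-{i + 1}" for i in range(n_decoys)]
    mapped_programs = sorted(effect_map)
    if not mapped_programs:
        raise ValueError("effect_map must tie at least one program to a factor")
    program_assignment = {m: mapped_programs[i % len(mapped_programs)]
                          for i, m in enumerate(mirna_ids)}

    C_true = simulate_programs(G, T, sparsity, rng_seed=s_prog)
    design, M_true = simulate_design_and_mixes(
        T, factors, replicates, effect_map, sigma_mix=sigma_mix, rng_seed=s_mix
    )
    C_mod, planted_targets, planted_effect = plant_mirna_regulation(
        C_true, mirna_ids, program_assignment, target_fraction, effect,
        rng_seed=s_plant, gene_ids=gene_ids,
    )
    # decoys: sites in sequence space, but no load effect
    n_targets = int(round(target_fraction * G))
    for d in decoy_ids:
        idx = rng.choice(G, size=n_targets, replace=False)
        planted_targets[d] = {gene_ids[i] for i in idx}

    # superposition coefficients: planted miRNAs live on mapped programs,
    # decoys on unmapped ones (or diffuse if every program is mapped)
    unmapped = [t for t in range(T) if t not in effect_map]
    coefficient_ids = mirna_ids + decoy_ids
    coeffs = np.zeros((len(coefficient_ids), T))
    for i, m in enumerate(mirna_ids):
        prog = program_assignment[m]
        sign = -1.0 if i % 2 else 1.0
        coeffs[i, prog] = sign * mirna_amplitude
        other = mapped_programs[(mapped_programs.index(prog) + 1) % len(mapped_programs)]
        coeffs[i, other] = 0.4 * mirna_amplitude * (1 if i % 3 else -1)
    for j, d in enumerate(decoy_ids):
        i = len(mirna_ids) + j
        if unmapped:
            coeffs[i, unmapped[j % len(unmapped)]] = mirna_amplitude
        else:
            coeffs[i] = rng.normal(0.0, 0.3, size=T)

    mrna, mirna = emit_expression(
        C_mod, M_true, noise_sd, coeffs, mirna_noise_sd,
        rng_seed=s_expr, gene_ids=gene_ids, sample_ids=design.sample_ids,
        mirna_ids=coefficient_ids,
    )

    if emit_seqs:
        mirna_seqs, utrs = emit_sequences(
            planted_targets, gene_ids, utr_length=utr_length, rng_seed=s_seq,
            contaminate=contaminate,
        )
    else:
        mirna_seqs, utrs = {}, {}

    # pathways: one planted set per mapped program (most negative target
    # loads, so the planted repression dominates), plus null sets
    target_union = sorted(set().union(*planted_targets.values()))
    gpos = {g: i for i, g in enumerate(gene_ids)}
    sets = {}
    pathway_assignments = {}
    for t in mapped_programs:
        pool = sorted(set().union(*(planted_targets[m] for m in mirna_ids
                                    if program_assignment[m] == t)))
        if len(pool) < pathway_size:
            continue
        load_order = np.argsort([C_mod[gpos[g], t] for g in pool])
        genes = {pool[i] for i in load_order[:pathway_size]}
        name = f"PLANTED_PW_P{t + 1}"
        sets[name] = (f"planted in program {t + 1}", genes)
        pathway_assignments[name] = {
            "genes": genes,
            "program": t,
            "true_median_load": float(np.median([C_mod[gpos[g], t] for g in genes])),
        }
    for j in range(n_null_pathways):
        genes = set(rng.choice(target_union, size=min(pathway_size, len(target_union)),
                               replace=False))
        sets[f"NULL_PW_{j + 1}"] = ("null pathway", genes)
    genesets = GeneSetCollection(sets)

    truth = SimulationTruth(
        gene_ids=gene_ids,
        sample_ids=design.sample_ids,
        mirna_ids=mirna_ids,
        decoy_ids=decoy_ids,
        C_true=C_true,
        C_modified=C_mod,
        M_true=M_true,
        planted_targets=planted_targets,
        planted_effect=planted_effect,
        program_assignment=program_assignment,
        mirna_coefficients=coeffs,
        coefficient_ids=coefficient_ids,
        effect_map=dict(effect_map),
        pathway_assignments=pathway_assignments,
        rng_seed=rng_seed,
    )
    return SyntheticBundle(mrna, mirna, design, mirna_seqs, utrs, genesets, truth)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write every bundle artifact as plain text; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": outdir / "mrna.tsv",
        "mirna": outdir / "mirna.tsv",
        "design": outdir / "design.tsv",
        "mirna_fasta": outdir / "mirnas.fa",
        "utr_fasta": outdir / "utrs.fa",
        "gmt": outdir / "pathways.gmt",
        "truth": outdir / "truth.json",
    }
    write_expression_table(bundle.mrna, paths["mrna"])
    write_expression_table(bundle.mirna, paths["mirna"])
    bundle.design.to_frame().to_csv(paths["design"], sep="\t", index=False)
    if bundle.mirna_seqs:
        write_fasta(bundle.mirna_seqs, paths["mirna_fasta"])
        write_fasta(bundle.utrs, paths["utr_fasta"])
    if len(bundle.genesets):
        write_gmt(bundle.genesets, paths["gmt"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth.to_json_dict(), fh, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
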