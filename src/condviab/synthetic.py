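"""Synthetic pharmacogenomic cohorts with known ground truth.

Emulates the structure of a CTRP/CCLE-style screen: per-cell-line basal
transcriptomes, compounds organized into mechanism-of-action (MOA) classes
that share planted target-gene sets, sigmoidal dose-response surfaces whose
IC50 is linked linearly to the z-scored expression of the target genes, and
a protein-interaction graph with cliques planted on each target set.  Every
pipeline stage (training, curve fitting, attribution, module analysis) can
therefore be checked against an oracle.

Model for the planted truth:

    log10 IC50(cell, compound) = alpha_compound + sum_{g in targets} w_g z_g(cell)
    viability(x) = 1 / (1 + (x / IC50)^h) + Gaussian noise, clipped at 0

so noiseless viability at x = IC50 is exactly 0.5, and the curve is the
log-logistic with b = h, c = 0, d = 1, e = IC50.

The per-compound potency offset alpha is *structure-determined*: it rides
the dominant chemotype axis (the first principal component of the cohort's
fingerprint matrix), so structurally similar compounds have similar
potencies, chemical structure carries real and learnable signal, and
ablating it (straw models) or withholding compounds has measurable
consequences.  MOA class and target-set assignment is deliberately
independent of structure, so structural similarity alone says nothing
about a compound's mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import json
import numpy as np
import pandas as pd

from .dose_response import default_grid
from .featurization import CompoundRecord

# ~50 public drug-like SMILES used to give synthetic compounds real,
# fingerprintable structures; identity -> SMILES assignment is seeded.
DRUGLIKE_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",                      # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                 # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                 # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",                         # paracetamol
    "Clc1ccccc1C2=NCc3ccccc3N2",                  # clonazepam-like core
    "CN1CCC[C@H]1c2cccnc2",                       # nicotine
    "OC(=O)c1ccccc1O",                            # salicylic acid
    "NC(=O)c1ccc(N)cc1",                          # aminobenzamide
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",               # naproxen
    "NC(N)=Nc1nc(CSCCN)cs1",                      # cimetidine-like
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",                 # procainamide
    "CN(C)CCCN1c2ccccc2Sc3ccccc13",               # promazine
    "OCC(O)COc1ccc(Cl)cc1",                       # chlorphenesin
    "CC(N)Cc1ccccc1",                             # amphetamine
    "COc1cc2c(cc1OC)CCN(C)CC2",                   # tetrahydroisoquinoline
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",             # atenolol
    "Clc1ccc(cc1)C(c2ccccc2)N3CCN(CCO)CC3",       # hydroxyzine-like
    "CN1CCN(CC1)c2ccc(cc2)C(=O)NC3CC3",           # arylpiperazine amide
    "OC(=O)CCc1ccccc1",                           # hydrocinnamic acid
    "Nc1ncnc2n(cnc12)C3OC(CO)C(O)C3O",            # adenosine
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",             # estradiol
    "CC(=O)OCC1=C(N2C(SC1)C(NC(=O)Cc3ccccc3)C2=O)C(=O)O",  # cephalosporin core
    "CN1C2CCC1CC(C2)OC(=O)C(CO)c3ccccc3",         # atropine
    "COc1ccc(CCN2CCC(CC2)Nc3nc4ccccc4n3Cc5ccc(F)cc5)cc1",  # astemizole-like
    "OC(CNC(C)C)c1ccc(O)c(O)c1",                  # isoprenaline
    "Cc1ccc(cc1)S(=O)(=O)NC(=O)NN2CCCCCC2",       # sulfonylurea
    "Clc1cccc(Cl)c1N=C2NCCN2",                    # clonidine
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",              # salbutamol
    "CN1CCCC1CCO",                                # aminoalcohol
    "COC(=O)c1ccccc1OC(=O)C",                     # methyl acetylsalicylate
    "NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O",         # hydrochlorothiazide
    "O=C1CCCCCN1",                                # caprolactam
    "CCOC(=O)c1ccc(N)cc1",                        # benzocaine
    "CCC(C)C1(CC)C(=O)NC(=O)NC1=O",               # barbiturate
    "CN(C)C(=N)NC(=N)N",                          # metformin
    "OC1CCCCC1N2CCCCC2",                          # cyclohexanol piperidine
    "Cc1ncc(COP(O)(O)=O)c(CN)c1O",                # pyridoxamine phosphate
    "OC(=O)C1CC(=O)NC(=O)N1",                     # hydroorotic acid
    "Nc1nc2ncc(CNc3ccc(cc3)C(=O)NC(CCC(O)=O)C(O)=O)nc2c(=O)[nH]1",  # folate
    "CC(CS)C(=O)N1CCCC1C(O)=O",                   # captopril
    "OCCN1CCN(CCCN2c3ccccc3Sc4ccc(Cl)cc24)CC1",   # perphenazine
    "COc1ccc2[nH]cc(CCNC(C)=O)c2c1",              # melatonin
    "Oc1ccc(CC2NCCc3cc(O)c(O)cc23)cc1O",          # tetrahydropapaveroline
    "CC(=O)SC1CC2=CC(=O)CCC2(C)C3CCC4(C)C(CCC4(C)O)C13",  # spironolactone-like
    "CN1CCC(CC1)=C2c3ccccc3CCc4ccccc24",          # cyproheptadine core
    "CCN(CC)C(=O)C1(c2ccccc2)CCN(C)CC1",          # normeperidine-like
    "COc1cc(cc(OC)c1OC)C(=O)OCC",                 # trimethoxybenzoate
    "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(O)=O", # penicillin G
    "Clc1ccccc1c2nnc(SCC(=O)O)n2c3ccccc3",        # triazole thioacetate
    "CN1CCN(CC1)C(=O)c2ccc(cc2)S(=O)(=O)N",       # sulfonamide piperazine
    "OCC1OC(O)C(O)C(O)C1O",                       # glucose
]


@dataclass
class SyntheticConfig:
    n_cell_lines: int = 8
    n_genes: int = 500
    n_compounds: int = 24
    n_moa_classes: int = 6
    targets_per_class: int = 3
    hill_slope: float = 2.0
    noise_sd: float = 0.05
    link_scale: float = 0.4       # sd of the cell-effect on log10 IC50, decades
    alpha_range: tuple = (-2.0, 1.5)   # per-compound log10 IC50 offset, uM
    background_degree: float = 3.0     # expected background PPI degree
    seed: int = 7

    def validate(self):
        if self.n_moa_classes > self.n_compounds:
            raise ValueError("n_moa_classes must be <= n_compounds")
        if self.targets_per_class < 1:
            raise ValueError("targets_per_class must be >= 1")
        if self.n_moa_classes * self.targets_per_class > self.n_genes:
            raise ValueError("not enough genes for disjoint target sets")
        if self.n_compounds > len(DRUGLIKE_SMILES):
            raise ValueError(
                f"at most {len(DRUGLIKE_SMILES)} compounds supported")


@dataclass
class GroundTruth:
    targets: dict[str, list[str]]           # compound -> target genes
    moa: dict[str, str]                     # compound -> MOA class
    class_targets: dict[str, list[str]]     # class -> target genes
    log10_ic50: pd.DataFrame                # cells x compounds
    hill_slope: float
    planted_modules: dict[str, list[str]]   # class -> clique node set

    def oracle_ic50(self, cell: str, compound: str) -> float:
        try:
            return float(10.0 ** self.log10_ic50.loc[cell, compound])
        except KeyError as err:
            raise KeyError(f"unknown ids ({cell!r}, {compound!r})") from err

    def oracle_targets(self, compound: str) -> set:
        if compound not in self.targets:
            raise KeyError(f"unknown compound {compound!r}")
        return set(self.targets[compound])

    def oracle_curve(self, cell: str, compound: str, grid) -> np.ndarray:
        ic50 = self.oracle_ic50(cell, compound)
        x = np.asarray(grid, dtype=np.float64)
        return 1.0 / (1.0 + (x / ic50) ** self.hill_slope)


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    expression: pd.DataFrame            # cells x genes, raw abundances
    compounds: list[CompoundRecord]
    compound_table: pd.DataFrame
    viability: pd.DataFrame             # sample_id, compound_id, conc, viability
    truth: GroundTruth
    ppi_edges: pd.DataFrame             # node_a, node_b, score

    def write(self, out_dir):
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        self.compound_table.to_csv(out / "compounds.csv", index=False)
        self.viability.to_csv(out / "viability.csv", index=False)
        self.ppi_edges.to_csv(out / "ppi.tsv", sep="\t", index=False)
        truth = {
            "targets": self.truth.targets,
            "moa": self.truth.moa,
            "class_targets": self.truth.class_targets,
            "hill_slope": self.truth.hill_slope,
            "planted_modules": self.truth.planted_modules,
            "log10_ic50": {
                cell: self.truth.log10_ic50.loc[cell].round(10).to_dict()
                for cell in self.truth.log10_ic50.index},
            "config": asdict(self.config),
        }
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; bit-exactly reproducible per seed."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    cells = [f"CL{i:03d}" for i in range(config.n_cell_lines)]
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    compounds = [f"CPD{i:03d}" for i in range(config.n_compounds)]
    classes = [f"MOA{i}" for i in range(config.n_moa_classes)]

    # transcriptomes: per-gene baseline + scaled standard-normal cell offset
    gene_mu = rng.normal(8.0, 2.0, size=config.n_genes)
    gene_sd = rng.uniform(0.5, 1.5, size=config.n_genes)
    Z = rng.standard_normal((config.n_cell_lines, config.n_genes))
    expression = pd.DataFrame(gene_mu + gene_sd * Z, index=cells,
                              columns=genes)

    # MOA classes with disjoint planted target sets and shared link weights
    shuffled = list(rng.permutation(genes))
    class_targets = {
        cls: sorted(shuffled[i * config.targets_per_class:
                             (i + 1) * config.targets_per_class])
        for i, cls in enumerate(classes)}
    class_weights = {
        cls: rng.normal(0.0, config.link_scale /
                        np.sqrt(config.targets_per_class),
                        size=config.targets_per_class)
        for cls in classes}

    moa = {comp: classes[i % len(classes)] for i, comp in enumerate(compounds)}
    targets = {comp: class_targets[moa[comp]] for comp in compounds}
    smiles_idx = rng.permutation(len(DRUGLIKE_SMILES))[:config.n_compounds]
    records = [CompoundRecord(compound_id=comp,
                              smiles=DRUGLIKE_SMILES[int(j)],
                              moa_class=moa[comp],
                              nominal_targets=list(targets[comp]))
               for comp, j in zip(compounds, smiles_idx)]

    # structure-determined potency: the dominant chemotype axis (first
    # principal component of the centered fingerprint matrix), standardized
    # across the cohort's compounds and mapped into the alpha range —
    # structurally similar compounds get similar potencies
    from .featurization import morgan_bits
    fps = np.stack([morgan_bits(r) for r in records])
    centered = fps - fps.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0] * np.sign(vt[0][np.argmax(np.abs(vt[0]))])
    raw_potency = centered @ pc1
    spread = raw_potency.std()
    z_potency = ((raw_potency - raw_potency.mean()) / spread
                 if spread > 0 else np.zeros_like(raw_potency))
    a_lo, a_hi = config.alpha_range
    alpha = np.clip((a_lo + a_hi) / 2 + (a_hi - a_lo) / 4 * z_potency,
                    a_lo, a_hi)

    # planted dose-response surfaces
    grid = default_grid()
    lo, hi = np.log10(grid[0]), np.log10(grid[-1])
    interior = (lo + 0.5, hi - 0.5)
    gene_pos = {g: i for i, g in enumerate(genes)}
    log_ic50 = np.empty((config.n_cell_lines, config.n_compounds))
    for j, comp in enumerate(compounds):
        cls = moa[comp]
        idx = [gene_pos[g] for g in class_targets[cls]]
        shift = Z[:, idx] @ class_weights[cls]
        log_ic50[:, j] = np.clip(alpha[j] + shift, *interior)
    log_ic50_df = pd.DataFrame(log_ic50, index=cells, columns=compounds)

    rows = []
    h = config.hill_slope
    for j, comp in enumerate(compounds):
        for i, cell in enumerate(cells):
            ic50 = 10.0 ** log_ic50[i, j]
            clean = 1.0 / (1.0 + (grid / ic50) ** h)
            noisy = clean + rng.normal(0.0, config.noise_sd, size=len(grid)) \
                if config.noise_sd > 0 else clean
            noisy = np.maximum(noisy, 0.0)
            for x, v in zip(grid, noisy):
                rows.append((cell, comp, float(x), float(v)))
    viability = pd.DataFrame(
        rows, columns=["sample_id", "compound_id", "concentration_um",
                       "viability"])

    # PPI graph: sparse random background + a clique on each target set
    p_bg = min(1.0, config.background_degree / max(config.n_genes - 1, 1))
    edges = {}
    n_bg = int(round(p_bg * config.n_genes * (config.n_genes - 1) / 2))
    for _ in range(n_bg):
        a, b = rng.integers(0, config.n_genes, size=2)
        if a == b:
            continue
        key = (genes[min(a, b)], genes[max(a, b)])
        edges.setdefault(key, float(rng.uniform(0.701, 1.0)))
    for cls in classes:
        tset = class_targets[cls]
        for i in range(len(tset)):
            for j in range(i + 1, len(tset)):
                key = (min(tset[i], tset[j]), max(tset[i], tset[j]))
                edges[key] = float(rng.uniform(0.85, 1.0))
    ppi = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(edges.items())],
        columns=["node_a", "node_b", "combined_score"])

    truth = GroundTruth(targets={c: list(t) for c, t in targets.items()},
                        moa=dict(moa),
                        class_targets={c: list(t)
                                       for c, t in class_targets.items()},
                        log10_ic50=log_ic50_df, hill_slope=h,
                        planted_modules={c: list(t)
                                         for c, t in class_targets.items()})
    table = pd.DataFrame({
        "compound_id": compounds,
        "smiles": [r.smiles for r in records],
        "moa_class": [r.moa_class for r in records],
        "targets": [";".join(r.nominal_targets) for r in records]})
    return SyntheticCohort(config=config, expression=expression,
                           compounds=records, compound_table=table,
                           viability=viability, truth=truth, ppi_edges=ppi)
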