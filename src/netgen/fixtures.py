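"""Synthetic inputs with planted ground truth for the whole pipeline.

Every generator is a pure function of (spec, master seed): the master seed
fans out to named substreams by stable hashing, so regenerating one fixture
never perturbs another. The fixtures emulate the formats the pipeline reads
— PPI edge list, GWAS summary statistics, per-type QTL tables, LD pairs,
gene annotation BED, expression matrix, drug-target table, and longitudinal
patient CSVs — each with a known planted signal: community structure in the
graph, QTL-linked evidence genes concentrated in one module, one tissue
with elevated expression of a chosen gene set, one drug targeted near the
evidence genes, and a patient cohort whose treated arm has a known true
hazard ratio under measured confounding.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from netgen.interactome import InteractomeGraph
from netgen.trials import PatientTables

TESTED_DRUG = "SIMX"
TESTED_ATC = "C10AA01"
COMPARATOR_DRUGS = ("COMPA", "COMPB")
COMPARATOR_ATCS = ("C10AA02", "C10AA03")
OUTCOME_ICD = "F03"       # dementia-like outcome
DISEASE_ICD = "G20"       # index disease
EXCLUSION_ICD = "G30"     # prior neurodegenerative diagnosis
ENCOUNTER_ICD = "Z00"     # generic visit marking the end of follow-up


def substream(master_seed: int, name: str) -> int:
    """Stable per-fixture RNG seed derived from the master seed (below 2^31)."""
    digest = hashlib.blake2b(f"{master_seed}/{name}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass
class GraphSpec:
    n_blocks: int = 2
    block_size: int = 30
    p_in: float = 0.3
    p_out: float = 0.01
    connect: bool = True  # patch-connect stray components

    def __post_init__(self) -> None:
        if self.p_in <= self.p_out:
            raise ValueError("planted partition requires p_in > p_out")


@dataclass
class EvidenceSpec:
    n_evidence: int = 10
    module: int = 0
    n_decoy_snps: int = 20
    n_ld_partners: int = 2   # clumpable partners per significant SNP
    n_proxies: int = 3       # strong-LD proxies among the significant SNPs


@dataclass
class ExpressionSpec:
    n_tissues: int = 8
    target_tissue: str = "SN"
    effect_size: float = 3.0   # sd units of elevation in the target tissue
    baseline_tpm: float = 10.0
    noise_sd: float = 2.0


@dataclass
class DrugSpec:
    n_drugs: int = 20
    targets_per_drug: int = 4
    planted_drug: str = "DRUG_CLOSE"


@dataclass
class CohortSpec:
    n_patients: int = 8000
    true_hr: float = 0.5
    treated_fraction: float = 0.25
    n_confounders: int = 4
    confounder_prevalence: float = 0.35
    confounder_treatment_logodds: float = 1.0
    confounder_hazard_logodds: float = 0.7
    baseline_hazard_per_year: float = 0.25
    censor_hazard_per_year: float = 0.15
    max_followup_years: float = 8.0
    n_age_violations: int = 10
    n_prior_dx_violations: int = 10


@dataclass
class FixtureSpec:
    seed: int = 0
    graph: GraphSpec = field(default_factory=GraphSpec)
    evidence: EvidenceSpec = field(default_factory=EvidenceSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    drugs: DrugSpec = field(default_factory=DrugSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)


# ---------------------------------------------------------------- interactome

def generate_interactome(spec: GraphSpec, seed: int) -> tuple[InteractomeGraph, dict[str, int]]:
    """Planted-partition graph over synthetic gene symbols plus the true labels."""
    rng = np.random.default_rng(substream(seed, "graph"))
    n = spec.n_blocks * spec.block_size
    names = [f"G{i:04d}" for i in range(n)]
    labels = {names[i]: i // spec.block_size for i in range(n)}
    block = np.arange(n) // spec.block_size
    prob = np.where(block[:, None] == block[None, :], spec.p_in, spec.p_out)
    draws = rng.random((n, n))
    iu, ju = np.triu_indices(n, k=1)
    keep = draws[iu, ju] < prob[iu, ju]
    g = nx.Graph()
    g.add_nodes_from(names)
    g.add_edges_from((names[i], names[j]) for i, j in zip(iu[keep], ju[keep]))
    if spec.connect:
        comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        for comp in comps[1:]:
            g.add_edge(min(comps[0]), min(comp))
    return InteractomeGraph(g), labels


def write_edge_list(g: InteractomeGraph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in g.graph.edges()):
            fh.write(f"{a}\t{b}\n")


# ------------------------------------------------------------------- genetics

GENE_SPACING = 100_000
GENE_LENGTH = 10_000


def gene_coordinates(genes: list[str]) -> pd.DataFrame:
    """Deterministic synthetic coordinates: genes tiled along chromosome 1."""
    rows = []
    for i, g in enumerate(sorted(genes)):
        start0 = i * GENE_SPACING + 1000  # BED 0-based
        rows.append({"chrom": "1", "start": start0, "end": start0 + GENE_LENGTH, "name": g})
    return pd.DataFrame(rows)


def generate_gwas_qtl(
    fix: FixtureSpec, g: InteractomeGraph, labels: dict[str, int]
) -> dict[str, pd.DataFrame]:
    """GWAS, QTL, LD and annotation tables with evidence planted in one module.

    Each planted evidence gene receives an eQTL link from a genome-wide
    significant SNP placed inside the gene body; a couple of evidence genes
    additionally get pQTL/sQTL links and meQTL/haQTL peaks overlapping the
    gene. Decoy SNPs with non-significant p-values and clumpable LD partner
    SNPs give the significance filter, clumping and proxy search real work.
    """
    spec = fix.evidence
    rng = np.random.default_rng(substream(fix.seed, "gwas_qtl"))
    module_genes = sorted(x for x, m in labels.items() if m == spec.module)
    evidence = sorted(rng.choice(module_genes, size=min(spec.n_evidence, len(module_genes)),
                                 replace=False))
    coords = gene_coordinates(list(g.nodes))
    pos_of = {r["name"]: (r["start"] + r["end"]) // 2 for _, r in coords.iterrows()}

    gwas_rows, ld_rows = [], []
    eqtl_rows, pqtl_rows, sqtl_rows, meqtl_rows, haqtl_rows = [], [], [], [], []
    snp_counter = 0

    def new_snp(pos: int, p: float) -> str:
        nonlocal snp_counter
        snp_counter += 1
        sid = f"rs{snp_counter:05d}"
        gwas_rows.append({"snp": sid, "chr": "1", "pos": pos, "p": p})
        return sid

    lead_snps: list[str] = []
    for k, gene in enumerate(evidence):
        pos = pos_of[gene]
        lead = new_snp(pos, 10.0 ** rng.uniform(-12, -8))
        lead_snps.append(lead)
        eqtl_rows.append({"snp": lead, "gene": gene})
        # clumpable partners: significant, nearby, correlated with the lead
        for _ in range(spec.n_ld_partners):
            partner = new_snp(pos + int(rng.integers(1_000, 200_000)),
                              10.0 ** rng.uniform(-8, -6))
            ld_rows.append({"snp_a": lead, "snp_b": partner,
                            "r2": float(rng.uniform(0.3, 0.7))})
            eqtl_rows.append({"snp": partner, "gene": gene})
        if k % 3 == 0:
            pqtl_rows.append({"snp": lead, "gene": gene})
        if k % 4 == 0:
            sqtl_rows.append({"snp": lead, "gene": gene})
        if k % 2 == 0:
            start0 = pos - 500  # BED interval overlapping the gene body
            meqtl_rows.append({"chrom": "1", "start": start0, "end": start0 + 1000, "snp": lead})
        if k % 2 == 1:
            start0 = pos - 800
            haqtl_rows.append({"chrom": "1", "start": start0, "end": start0 + 1600, "snp": lead})

    # strong-LD proxies among significant SNPs (distinct positions, r2 > 0.8)
    for lead in lead_snps[: spec.n_proxies]:
        proxy = new_snp(pos_of[evidence[0]] + int(rng.integers(200_000, 400_000)),
                        10.0 ** rng.uniform(-8, -6))
        ld_rows.append({"snp_a": lead, "snp_b": proxy, "r2": float(rng.uniform(0.85, 0.99))})

    # decoys: non-significant SNPs, some with QTL links that must never survive
    decoy_genes = sorted(set(g.nodes) - set(evidence))
    for d in range(spec.n_decoy_snps):
        gene = decoy_genes[int(rng.integers(len(decoy_genes)))]
        sid = new_snp(pos_of[gene], float(rng.uniform(1e-4, 1.0)))
        if d % 2 == 0:
            eqtl_rows.append({"snp": sid, "gene": gene})

    return {
        "gwas": pd.DataFrame(gwas_rows),
        "eqtl": pd.DataFrame(eqtl_rows),
        "pqtl": pd.DataFrame(pqtl_rows),
        "sqtl": pd.DataFrame(sqtl_rows),
        "meqtl": pd.DataFrame(meqtl_rows),
        "haqtl": pd.DataFrame(haqtl_rows),
        "ld": pd.DataFrame(ld_rows),
        "annotation": coords,
        "evidence_genes": pd.DataFrame({"gene": evidence}),
    }


# ----------------------------------------------------------------- expression

def generate_expression(
    fix: FixtureSpec, genes: list[str], planted: list[str]
) -> pd.DataFrame:
    """Genes x tissues TPM with ``planted`` genes elevated in the target tissue.

    Non-target tissues are exchangeable draws around a common baseline; the
    planted genes' target-tissue values sit ``effect_size`` noise-sd above it.
    """
    spec = fix.expression
    rng = np.random.default_rng(substream(fix.seed, "expression"))
    tissues = [spec.target_tissue] + [f"T{i:02d}" for i in range(1, spec.n_tissues)]
    genes = sorted(genes)
    base = np.abs(rng.normal(spec.baseline_tpm, spec.noise_sd, size=(len(genes), len(tissues))))
    df = pd.DataFrame(base, index=pd.Index(genes, name="gene"), columns=tissues)
    planted_in = [x for x in planted if x in df.index]
    df.loc[planted_in, spec.target_tissue] += spec.effect_size * spec.noise_sd
    return df


# --------------------------------------------------------------------- drugs

def generate_drug_targets(
    fix: FixtureSpec, g: InteractomeGraph, disease_genes: list[str]
) -> pd.DataFrame:
    """Drug-target table with one drug planted adjacent to the disease genes.

    The planted drug's targets are disease genes and their direct neighbors,
    so its proximity Z should be strongly negative; the remaining drugs draw
    targets uniformly from the network.
    """
    spec = fix.drugs
    rng = np.random.default_rng(substream(fix.seed, "drugs"))
    disease_in = [x for x in disease_genes if x in g.graph]
    near_pool = sorted(set(disease_in) | {n for d in disease_in for n in g.graph.neighbors(d)})
    rows = []
    planted_targets = rng.choice(near_pool, size=min(spec.targets_per_drug, len(near_pool)),
                                 replace=False)
    for t in sorted(planted_targets):
        rows.append({"drug_id": spec.planted_drug, "drug_name": spec.planted_drug.lower(),
                     "target_symbol": t, "atc_codes": "N07XX01", "approved": 1})
    all_nodes = list(g.nodes)
    for d in range(spec.n_drugs - 1):
        drug_id = f"DRUG_{d:03d}"
        targets = rng.choice(all_nodes, size=spec.targets_per_drug, replace=False)
        approved = int(d % 4 != 0)  # a quarter unapproved
        for t in sorted(targets):
            rows.append({"drug_id": drug_id, "drug_name": drug_id.lower(),
                         "target_symbol": t, "atc_codes": f"A{d:02d}AA01",
                         "approved": approved})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- EHR

def generate_ehr_cohort(fix: FixtureSpec) -> tuple[PatientTables, dict]:
    """Longitudinal patient tables with a planted treatment effect.

    Measured binary confounders raise both the probability of receiving the
    tested drug and the outcome hazard, so the naive (unmatched) hazard
    ratio is biased away from the truth while the matched pipeline can
    recover it. Event times are exponential with the treated-arm hazard
    multiplied by ``true_hr``; censoring is exponential, truncated at the
    maximum follow-up. Known eligibility violations (too young at first
    diagnosis, prior exclusion diagnosis) are planted as extra patients.
    """
    spec = fix.cohort
    rng = np.random.default_rng(substream(fix.seed, "ehr"))
    n = spec.n_patients
    origin = pd.Timestamp("2010-01-01")

    ids = [f"P{i:06d}" for i in range(n)]
    sex = rng.choice(["M", "F"], size=n)
    race = rng.choice(["white", "black", "asian", "other"], size=n)
    age_at_dx = rng.uniform(55, 85, size=n)
    dx_offset_days = rng.integers(0, 5 * 365, size=n)
    first_dx = origin + pd.to_timedelta(dx_offset_days, unit="D")
    birth = first_dx - pd.to_timedelta((age_at_dx * 365.25).astype(int), unit="D")

    conf = (rng.random((n, spec.n_confounders)) < spec.confounder_prevalence).astype(float)
    logit = (
        np.log(spec.treated_fraction / (1 - spec.treated_fraction))
        - spec.confounder_treatment_logodds * spec.confounder_prevalence * spec.n_confounders
        + spec.confounder_treatment_logodds * conf.sum(axis=1)
    )
    treated = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    index_offset = rng.integers(30, 365, size=n)
    index_date = first_dx + pd.to_timedelta(index_offset, unit="D")

    hazard = spec.baseline_hazard_per_year * np.exp(
        spec.confounder_hazard_logodds * (conf.sum(axis=1) - spec.confounder_prevalence
                                          * spec.n_confounders)
    )
    hazard = hazard * np.where(treated, spec.true_hr, 1.0)
    event_years = rng.exponential(1.0 / hazard)
    censor_years = np.minimum(rng.exponential(1.0 / spec.censor_hazard_per_year, size=n),
                              spec.max_followup_years)
    observed_years = np.minimum(event_years, censor_years)
    had_event = event_years <= censor_years

    patients = pd.DataFrame({"id": ids, "birth_date": birth, "sex": sex, "race": race})
    dx_rows = [{"id": ids[i], "icd": DISEASE_ICD, "date": first_dx[i]} for i in range(n)]
    rx_rows = []
    comorb_codes = [f"I{10 + c}" for c in range(spec.n_confounders)]
    for i in range(n):
        init = first_dx[i] - pd.Timedelta(days=182)
        for c in range(spec.n_confounders):
            if conf[i, c]:
                # recorded inside the baseline window [initiation, index)
                lag = int(rng.integers(0, max(1, (index_date[i] - init).days)))
                dx_rows.append({"id": ids[i], "icd": comorb_codes[c], "date": init + pd.Timedelta(days=lag)})
        drug = TESTED_DRUG if treated[i] else COMPARATOR_DRUGS[int(rng.integers(len(COMPARATOR_DRUGS)))]
        atc = TESTED_ATC if treated[i] else COMPARATOR_ATCS[int(rng.integers(len(COMPARATOR_ATCS)))]
        rx_rows.append({"id": ids[i], "ingredient": drug, "atc": atc, "date": index_date[i]})
        end = index_date[i] + pd.Timedelta(days=int(observed_years[i] * 365.25) + 1)
        if had_event[i]:
            dx_rows.append({"id": ids[i], "icd": OUTCOME_ICD, "date": end})
        else:
            dx_rows.append({"id": ids[i], "icd": ENCOUNTER_ICD, "date": end})

    # planted eligibility violations
    violation_ids = {"age": [], "prior_dx": []}
    v = 0
    for _ in range(spec.n_age_violations):
        pid = f"V{v:06d}"; v += 1
        violation_ids["age"].append(pid)
        dxd = origin + pd.Timedelta(days=int(rng.integers(0, 1000)))
        patients = pd.concat([patients, pd.DataFrame([{
            "id": pid, "birth_date": dxd - pd.Timedelta(days=int(45 * 365.25)),
            "sex": "F", "race": "white"}])], ignore_index=True)
        dx_rows.append({"id": pid, "icd": DISEASE_ICD, "date": dxd})
    for _ in range(spec.n_prior_dx_violations):
        pid = f"V{v:06d}"; v += 1
        violation_ids["prior_dx"].append(pid)
        dxd = origin + pd.Timedelta(days=int(rng.integers(1000, 2000)))
        patients = pd.concat([patients, pd.DataFrame([{
            "id": pid, "birth_date": dxd - pd.Timedelta(days=int(70 * 365.25)),
            "sex": "M", "race": "white"}])], ignore_index=True)
        dx_rows.append({"id": pid, "icd": EXCLUSION_ICD, "date": dxd - pd.Timedelta(days=400)})
        dx_rows.append({"id": pid, "icd": DISEASE_ICD, "date": dxd})

    tables = PatientTables(
        patients=patients,
        diagnoses=pd.DataFrame(dx_rows),
        prescriptions=pd.DataFrame(rx_rows),
    )
    truth = {
        "true_hr": spec.true_hr,
        "treated_ids": [ids[i] for i in range(n) if treated[i]],
        "confounders": pd.DataFrame(conf, index=ids,
                                    columns=[f"conf_{c}" for c in range(spec.n_confounders)]),
        "comorbidity_codes": {f"conf_{c}": (comorb_codes[c],) for c in range(spec.n_confounders)},
        "violation_ids": violation_ids,
    }
    return tables, truth


DEFAULT_N_EMULATIONS_FOR_FIXTURES = 20


def default_trial_spec(truth: dict, min_users: int = 20,
                       n_emulations: int = DEFAULT_N_EMULATIONS_FOR_FIXTURES) -> "TrialSpec":
    """TrialSpec wired to the planted cohort's code sets."""
    from netgen.trials import TrialSpec

    return TrialSpec(
        drug=TESTED_DRUG,
        outcome_codes=(OUTCOME_ICD,),
        disease_codes=(DISEASE_ICD,),
        exclusion_codes=(EXCLUSION_ICD,),
        comorbidity_codes=truth["comorbidity_codes"],
        medication_ingredients=(),
        min_users=min_users,
        n_emulations=n_emulations,
    )


# ---------------------------------------------------------------- file output

def write_all(fix: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate every fixture and write it in the format the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    g, labels = generate_interactome(fix.graph, fix.seed)
    paths["ppi"] = out / "ppi_edges.tsv"
    write_edge_list(g, paths["ppi"])
    paths["labels"] = out / "planted_labels.tsv"
    pd.Series(labels, name="module").rename_axis("gene").to_frame().to_csv(
        paths["labels"], sep="\t")

    tabs = generate_gwas_qtl(fix, g, labels)
    for key in ("gwas", "eqtl", "pqtl", "sqtl", "ld", "evidence_genes"):
        paths[key] = out / f"{key}.tsv"
        tabs[key].to_csv(paths[key], sep="\t", index=False)
    for key in ("meqtl", "haqtl"):
        paths[key] = out / f"{key}.bed"
        tabs[key].to_csv(paths[key], sep="\t", index=False, header=False)
    paths["annotation"] = out / "genes.bed"
    tabs["annotation"].to_csv(paths["annotation"], sep="\t", index=False, header=False)

    evidence = list(tabs["evidence_genes"]["gene"])
    expr = generate_expression(fix, list(g.nodes), evidence)
    paths["expression"] = out / "expression_tpm.tsv"
    expr.to_csv(paths["expression"], sep="\t")

    drug_df = generate_drug_targets(fix, g, evidence)
    paths["drug_targets"] = out / "drug_targets.tsv"
    drug_df.to_csv(paths["drug_targets"], sep="\t", index=False)

    tables, _ = generate_ehr_cohort(fix)
    paths["patients"] = out / "patients.csv"
    paths["diagnoses"] = out / "diagnoses.csv"
    paths["prescriptions"] = out / "prescriptions.csv"
    tables.patients.to_csv(paths["patients"], index=False)
    tables.diagnoses.to_csv(paths["diagnoses"], index=False)
    tables.prescriptions.to_csv(paths["prescriptions"], index=False)
    return paths
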