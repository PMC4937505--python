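"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study conditions at desk scale: a protein
database stands in for the human proteome; neo-C-terminal Asp peptides with
TMT6 reporter intensities follow five planted kinetic archetypes over the
0-72 h tunicamycin time course; decoy PSMs carry lower score features;
RNA-seq counts are negative-binomial with transcription-factor target sets
up-regulated only in the caspase-inhibitor arm at late time points while
each factor's own transcript stays below a 2-fold change.  Fixed seeds give
byte-identical outputs; every record maps to exactly one truth label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import TriadProfile
from .design import CSP_ARCHETYPES, DEFAULT_DESIGN, StudyDesign
from .cleavage import PROTEASE_P1, AMINO_ACIDS
from .quantify import TMT6_REPORTER_MZ

__all__ = [
    "gen_protein_db",
    "digest_candidates",
    "gen_cleavage_psms",
    "gen_reporter_spectra",
    "gen_trajectories",
    "gen_counts",
    "gen_tf_collection",
    "gen_triads",
    "gen_known_sites",
]

#: Default regulatory-mode mixture for triad generation.  Most substrates in
#: the study are protein-down (346/445), with transcript-up (degradation) and
#: transcript-down (transcription-coupled) patterns more prevalent than the
#: flat-transcript direct pattern; co-up-regulated substrates are a minority.
DEFAULT_MODE_WEIGHTS = {
    "caspase_degradation": 0.30,
    "co_upregulated": 0.20,
    "direct_caspase": 0.20,
    "transcription_coupled": 0.30,
}


# ---------------------------------------------------------------------------
# Protein database
# ---------------------------------------------------------------------------

def gen_protein_db(
    n_proteins: int,
    length_range: tuple[int, int] = (50, 500),
    seed: int | None = None,
) -> dict[str, str]:
    """Random protein database with unique accessions.

    Sequences draw uniformly from the 20 canonical residues, so internal
    aspartates occur at the ~5% background rate and cleavage sites can be
    planted in essentially every protein; the >= 30% internal-Asp guarantee
    is checked explicitly.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))) or lo < 8 or hi < lo:
        raise ValueError(f"invalid length range {length_range!r}: need 8 <= min <= max")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    db: dict[str, str] = {}
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aas, size=length))
        db[f"SYN{i:05d}"] = seq
    with_internal_d = sum("D" in s[1:-1] for s in db.values())
    if with_internal_d < 0.3 * n_proteins:
        raise RuntimeError("generated database violates the internal-Asp guarantee")
    return db


# ---------------------------------------------------------------------------
# Cleavage PSMs
# ---------------------------------------------------------------------------

@dataclass
class PlantedPeptide:
    peptide: str
    accession: str
    p1_position: int  # 1-based
    protease: str
    archetype: str = ""


def digest_candidates(
    db: dict[str, str],
    protease: str = "trypsin",
    min_len: int = 7,
    max_len: int = 30,
    max_missed: int = 4,
) -> list[PlantedPeptide]:
    """Enumerate digest-valid neo-C-terminal Asp peptides of a database.

    A candidate spans [start, p1] where protein[p1-1] == 'D', the residue
    before ``start`` is a protease cut residue (or protein N-terminus) and
    internal K/R/D count <= ``max_missed``.
    """
    cut_n = PROTEASE_P1[protease]
    cut_all = cut_n | {"D"}
    out: list[PlantedPeptide] = []
    for acc in sorted(db):
        prot = db[acc]
        for i, aa in enumerate(prot):
            if aa != "D":
                continue
            for st in range(max(0, i - max_len + 1), i - min_len + 2):
                if st > 0 and prot[st - 1] not in cut_n:
                    continue
                pep = prot[st : i + 1]
                if len(pep) < min_len:
                    continue
                if sum(1 for a in pep[:-1] if a in cut_all) > max_missed:
                    continue
                out.append(PlantedPeptide(pep, acc, i + 1, protease))
    return out


def gen_cleavage_psms(
    db: dict[str, str],
    design: StudyDesign = DEFAULT_DESIGN,
    n_psms: int = 1000,
    n_peptides: int = 300,
    archetypes: dict[str, np.ndarray] | None = None,
    noise_sd: float = 0.2,
    decoy_fraction: float = 0.3,
    false_target_fraction: float = 0.0,
    base_intensity: float = 2e5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """PSM table with planted kinetic archetypes and decoy score features.

    Target peptides are digest-valid neo-C-terminal Asp products of ``db``
    (trypsin and chymotrypsin pools mixed); each peptide is assigned one of
    the kinetic ``archetypes`` and its PSMs carry reporter intensities
    ``base * template * exp(N(0, noise_sd))`` per channel (lognormal
    multiplicative noise on a positive, right-skewed scale).  Decoys are
    sequence-reversed targets keeping the C-terminal Asp, with score
    features from a lower-scoring distribution.  ``false_target_fraction``
    of the target PSMs instead draw their scores from the decoy distribution
    (incorrect identifications with known labels, for FDR benchmarking).

    Exactly ``round(decoy_fraction * n_psms)`` decoy rows are produced.
    Returns (psm table, truth) where truth maps every spectrum and peptide
    to its labels.
    """
    archetypes = archetypes or CSP_ARCHETYPES
    cands = digest_candidates(db, "trypsin") + digest_candidates(db, "chymotrypsin")
    if not cands:
        raise ValueError("database contains no digest-valid Asp peptide")
    rng = np.random.default_rng(seed)
    n_decoys = int(round(decoy_fraction * n_psms))
    n_targets = n_psms - n_decoys
    if n_targets < 1:
        raise ValueError("decoy_fraction leaves no target PSMs")
    # unique peptides, at most one per (peptide) string
    order = rng.permutation(len(cands))
    chosen: list[PlantedPeptide] = []
    seen: set[str] = set()
    for k in order:
        c = cands[k]
        if c.peptide in seen:
            continue
        seen.add(c.peptide)
        chosen.append(c)
        if len(chosen) == min(n_peptides, n_targets):
            break
    arch_names = sorted(archetypes)
    for j, c in enumerate(chosen):
        c.archetype = arch_names[j % len(arch_names)]
    n_false = int(round(false_target_fraction * n_targets))
    cols = design.channel_columns()
    rows = []
    truth_psm = []
    for i in range(n_targets):
        pep = chosen[i % len(chosen)]
        template = archetypes[pep.archetype]
        base = base_intensity * rng.lognormal(0.0, 0.3)
        if noise_sd > 0:
            reporters = base * template * rng.lognormal(0.0, noise_sd, size=len(template))
        else:
            reporters = base * template
        is_false = i < n_false
        sid = f"scan{i:06d}"
        if is_false:
            score = rng.normal(45, 8)
            delta = abs(rng.normal(5, 3))
            ppm = rng.normal(0, 5)
        else:
            score = rng.normal(70, 8)
            delta = abs(rng.normal(15, 5))
            ppm = rng.normal(0, 2)
        missed = sum(1 for a in pep.peptide[:-1] if a in PROTEASE_P1[pep.protease] | {"D"})
        rows.append(
            [sid, pep.peptide, pep.accession, 0, score, delta, ppm, missed,
             int(rng.choice([2, 3], p=[0.7, 0.3])), *reporters]
        )
        truth_psm.append([sid, pep.peptide, "false_target" if is_false else "target",
                          pep.archetype])
    for i in range(n_decoys):
        src = chosen[int(rng.integers(len(chosen)))]
        dpep = src.peptide[:-1][::-1] + "D"
        base = base_intensity * rng.lognormal(0.0, 0.3)
        reporters = base * rng.lognormal(0.0, max(noise_sd, 0.1), size=len(cols))
        sid = f"scan{n_targets + i:06d}"
        rows.append(
            [sid, dpep, f"DECOY_{src.accession}", 1, rng.normal(45, 8),
             abs(rng.normal(5, 3)), rng.normal(0, 5), int(rng.integers(0, 5)),
             int(rng.choice([2, 3], p=[0.7, 0.3])), *reporters]
        )
        truth_psm.append([sid, dpep, "decoy", ""])
    psms = pd.DataFrame(
        rows,
        columns=["spectrum_id", "peptide", "proteins", "decoy", "score",
                 "delta_score", "ppm_error", "missed_cleavages", "charge", *cols],
    )
    truth = {
        "psms": pd.DataFrame(truth_psm, columns=["spectrum_id", "peptide", "kind", "archetype"]),
        "peptides": pd.DataFrame(
            {
                "peptide": [c.peptide for c in chosen],
                "accession": [c.accession for c in chosen],
                "p1_position": [c.p1_position for c in chosen],
                "protease": [c.protease for c in chosen],
                "archetype": [c.archetype for c in chosen],
            }
        ),
    }
    return psms, truth


# ---------------------------------------------------------------------------
# Reporter-region peak lists
# ---------------------------------------------------------------------------

def gen_reporter_spectra(
    n_spectra: int,
    design: StudyDesign = DEFAULT_DESIGN,
    jitter_ppm: float = 8.0,
    n_distractors: int = 6,
    secondary_in_window: bool = True,
    seed: int | None = None,
):
    """Reporter-region peak lists with known planted channel intensities.

    Each spectrum carries one planted peak per channel within
    ``jitter_ppm`` of the theoretical reporter m/z, optional lower-intensity
    secondary peaks inside the same window (exercising the highest-peak
    rule without changing the answer) and distractor peaks strictly outside
    the 20 ppm windows.  Returns (spectra, planted intensity matrix).
    """
    from .quantify import ReporterSpectrum

    rng = np.random.default_rng(seed)
    theo = np.array([TMT6_REPORTER_MZ[c] for c in design.channels])
    spectra = []
    planted = np.empty((n_spectra, len(theo)))
    for s in range(n_spectra):
        intens = rng.lognormal(np.log(1e4), 1.0, size=len(theo))
        planted[s] = intens
        mz = list(theo * (1 + rng.uniform(-jitter_ppm, jitter_ppm, size=len(theo)) / 1e6))
        inten = list(intens)
        if secondary_in_window:
            for j in range(len(theo)):
                if rng.random() < 0.5:
                    mz.append(theo[j] * (1 + rng.uniform(-jitter_ppm, jitter_ppm) / 1e6))
                    inten.append(intens[j] * rng.uniform(0.1, 0.9))
        for _ in range(n_distractors):
            j = int(rng.integers(len(theo)))
            off = rng.uniform(30, 400) * rng.choice([-1, 1])
            mz.append(theo[j] * (1 + off / 1e6))
            inten.append(rng.lognormal(np.log(1e4), 1.0))
        spectra.append(ReporterSpectrum(f"spec{s:06d}", np.array(mz), np.array(inten)))
    return spectra, planted


# ---------------------------------------------------------------------------
# Trajectory sets
# ---------------------------------------------------------------------------

def gen_trajectories(
    n: int,
    archetypes: dict[str, np.ndarray] | None = None,
    noise_sd: float = 0.3,
    seed: int | None = None,
    prefix: str = "feat",
) -> tuple[pd.DataFrame, pd.Series]:
    """Standardized archetype templates plus Gaussian noise.

    Archetypes are assigned round-robin (balanced classes).  Returns the
    trajectory matrix and the truth labels.
    """
    archetypes = archetypes or CSP_ARCHETYPES
    names = sorted(archetypes)
    rng = np.random.default_rng(seed)
    templates = {
        k: (v - v.mean()) / v.std() for k, v in archetypes.items()
    }
    labels = [names[i % len(names)] for i in range(n)]
    rng.shuffle(labels)
    X = np.stack([templates[lab] for lab in labels])
    X = X + rng.normal(0.0, noise_sd, size=X.shape)
    idx = [f"{prefix}{i:05d}" for i in range(n)]
    return (
        pd.DataFrame(X, index=idx, columns=[f"t{j}" for j in range(X.shape[1])]),
        pd.Series(labels, index=idx, name="archetype"),
    )


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def gen_counts(
    genes: list[str],
    design: StudyDesign = DEFAULT_DESIGN,
    time_points: tuple[float, ...] | None = None,
    treatments: tuple[str, ...] | None = None,
    replicates: int | None = None,
    planted_sets: dict[str, list[str]] | None = None,
    dual_tf_sets: list[str] | None = None,
    tf_map: dict[str, str] | None = None,
    target_up_fc: float = 4.0,
    tf_flat_fc: float = 2.0,
    tf_own_fc_limit: float = 1.25,
    planted_de: dict[str, float] | None = None,
    effect_from_h: float = 24.0,
    dispersion: float = 0.02,
    base_mean: float = 150.0,
    time_archetypes: dict[str, np.ndarray] | None = None,
    time_amplitude: float = 0.0,
    archetype_override: dict[str, str] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict]:
    """Negative-binomial count matrix with planted differential expression.

    Sample grid: ``treatments`` x ``time_points`` x ``replicates`` (defaults
    from ``design``: TM/TMZ arms, 0/8/24/72 h, 3 replicates).  Per gene a
    lognormal baseline mean; optionally a kinetic time factor
    ``2**(amplitude * z(template))`` from ``time_archetypes``.  Genes in the
    target sets of ``dual_tf_sets`` are multiplied by ``target_up_fc`` in
    the inhibitor arm at time points >= ``effect_from_h``; each dual TF's
    own gene gets an inhibitor-arm factor drawn uniformly within
    [1/(0.7*tf_flat_fc), 0.7*tf_flat_fc] so its realized fold change stays
    below ``tf_flat_fc``.  ``planted_de`` maps further genes to inhibitor-arm
    fold changes.  Counts are NB with Var = mu + dispersion * mu^2.

    Returns (counts, gene lengths, sample table, truth).
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    time_points = time_points or design.rna_time_points_h
    treatments = treatments or design.treatments
    replicates = replicates or design.rna_replicates
    planted_sets = planted_sets or {}
    dual_tf_sets = dual_tf_sets or []
    tf_map = tf_map or {}
    planted_de = dict(planted_de or {})
    rng = np.random.default_rng(seed)
    G = len(genes)
    base = base_mean * rng.lognormal(0.0, 1.0, size=G)
    lengths = pd.Series(rng.integers(500, 5001, size=G), index=genes, name="length")

    gene_pos = {g: i for i, g in enumerate(genes)}
    # kinetic time factors (stress-response shapes shared by both arms)
    arch_assign: dict[str, str] = {}
    time_factor = np.ones((G, len(time_points)))
    if time_archetypes and time_amplitude > 0:
        names = sorted(time_archetypes)
        full_t = np.asarray(design.time_points_h, dtype=float)
        override = archetype_override or {}
        for i, g in enumerate(genes):
            nm = override.get(g, names[i % len(names)])
            arch_assign[g] = nm
            tmpl = np.asarray(time_archetypes[nm], dtype=float)
            z = (tmpl - tmpl.mean()) / tmpl.std()
            # interpolate the 6-point template onto this design's time grid
            zi = np.interp(np.asarray(time_points, dtype=float), full_t, z)
            time_factor[i] = 2.0 ** (time_amplitude * zi)

    # inhibitor-arm effects
    inhibitor_fc = np.ones(G)
    target_genes: set[str] = set()
    for set_name in dual_tf_sets:
        for g in planted_sets.get(set_name, []):
            if g in gene_pos:
                inhibitor_fc[gene_pos[g]] = target_up_fc
                target_genes.add(g)
    # Dual TFs keep a near-flat own transcript: planted fold changes within
    # tf_own_fc_limit (default 1.25, the magnitude range of the reported
    # exemplars) so that the realized fold change stays below tf_flat_fc
    # despite count-sampling noise; TF genes also get a quantifiable
    # baseline (at least the global base mean).
    tf_own_fc: dict[str, float] = {}
    for tf, set_name in sorted(tf_map.items()):
        if tf in gene_pos and set_name in dual_tf_sets:
            fc = float(rng.uniform(1.0 / tf_own_fc_limit, tf_own_fc_limit))
            inhibitor_fc[gene_pos[tf]] = fc
            tf_own_fc[tf] = fc
            base[gene_pos[tf]] = max(base[gene_pos[tf]], base_mean)
    for g, fc in planted_de.items():
        if g in gene_pos:
            inhibitor_fc[gene_pos[g]] = fc

    samples = []
    cols = {}
    for arm in treatments:
        for it, t in enumerate(time_points):
            for r in range(1, replicates + 1):
                name = f"{arm}_t{int(t)}_r{r}"
                mu = base * time_factor[:, it]
                if arm == treatments[-1] and len(treatments) > 1 and t >= effect_from_h:
                    mu = mu * inhibitor_fc
                if dispersion < 1e-8:
                    counts = rng.poisson(mu)
                else:
                    nb_n = 1.0 / dispersion
                    nb_p = nb_n / (nb_n + mu)
                    counts = rng.negative_binomial(nb_n, nb_p)
                cols[name] = counts
                samples.append({"sample": name, "treatment": arm, "time_h": t, "replicate": r})
    counts_df = pd.DataFrame(cols, index=genes)
    sample_df = pd.DataFrame(samples)
    truth = {
        "target_genes": sorted(target_genes),
        "planted_de": planted_de,
        "tf_own_fc": tf_own_fc,
        "dual_tf_sets": list(dual_tf_sets),
        "time_archetype": arch_assign,
    }
    return counts_df, lengths, sample_df, truth


def gen_tf_collection(
    genes: list[str],
    n_sets: int = 50,
    set_size: int = 30,
    n_dual: int = 5,
    seed: int | None = None,
) -> tuple[dict[str, list[str]], dict[str, str], list[str]]:
    """TF target-set collection (GMT-style) with planted dual-regulated TFs.

    Each set gets a distinct TF gene (drawn from ``genes``, excluded from
    all target sets); the first ``n_dual`` sets (after shuffling) are marked
    dual-regulated.  Returns (sets, tf->set map, dual set names).
    """
    rng = np.random.default_rng(seed)
    if n_sets * (set_size + 1) > len(genes):
        raise ValueError("gene pool too small for the requested collection")
    pool = list(genes)
    rng.shuffle(pool)
    tf_genes = pool[:n_sets]
    rest = pool[n_sets:]
    sets: dict[str, list[str]] = {}
    tf_map: dict[str, str] = {}
    for k in range(n_sets):
        name = f"TFSET_{k:03d}"
        # disjoint target sets: unambiguous truth labels per gene
        sets[name] = sorted(rest[k * set_size : (k + 1) * set_size])
        tf_map[tf_genes[k]] = name
    dual = [f"TFSET_{k:03d}" for k in range(n_dual)]
    return sets, tf_map, dual


# ---------------------------------------------------------------------------
# Regulatory triads
# ---------------------------------------------------------------------------

def gen_triads(
    n: int = 400,
    noise_sd: float = 0.25,
    mode_weights: dict[str, float] | None = None,
    seed: int | None = None,
) -> tuple[list[TriadProfile], pd.Series]:
    """Cleavage/protein/transcript triads with planted regulatory modes.

    Layer templates are standardized monotone ramps (up/down) or exact
    zeros (flat), plus N(0, noise_sd) per point.  Mode layout:
    caspase_degradation = (transcript up, protein down, cleavage up);
    co_upregulated = all up; direct_caspase = (flat, down, up);
    transcription_coupled = (down, down, up).
    """
    weights = mode_weights or DEFAULT_MODE_WEIGHTS
    rng = np.random.default_rng(seed)
    ramp = np.linspace(0.0, 1.0, 6)
    up = (ramp - ramp.mean()) / ramp.std()
    down = -up
    flat = np.zeros(6)
    layout = {
        "caspase_degradation": (up, down, up),
        "co_upregulated": (up, up, up),
        "direct_caspase": (flat, down, up),
        "transcription_coupled": (down, down, up),
    }
    modes = sorted(weights)
    probs = np.array([weights[m] for m in modes], dtype=float)
    probs = probs / probs.sum()
    assigned = rng.choice(modes, size=n, p=probs)
    triads, labels = [], []
    for i, mode in enumerate(assigned):
        t, p, c = layout[mode]
        gene = f"gene{i:05d}"
        triads.append(
            TriadProfile(
                gene=gene,
                transcript=t + rng.normal(0, noise_sd, 6) if noise_sd > 0 else t.copy(),
                protein=p + rng.normal(0, noise_sd, 6) if noise_sd > 0 else p.copy(),
                cleavage=c + rng.normal(0, noise_sd, 6) if noise_sd > 0 else c.copy(),
            )
        )
        labels.append(mode)
    return triads, pd.Series(labels, index=[t.gene for t in triads], name="mode")


# ---------------------------------------------------------------------------
# Known-site reference lists
# ---------------------------------------------------------------------------

def gen_known_sites(
    sites: pd.DataFrame,
    shared_fraction: float = 0.4,
    n_extra: int = 50,
    n_references: int = 2,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Flat-file stand-ins for known cleavage-site repositories.

    Each reference samples ``shared_fraction`` of the study sites (exact
    coordinates) and adds ``n_extra`` sites at coordinates not present in
    the study list.
    """
    rng = np.random.default_rng(seed)
    study = list(zip(sites["accession"], sites["p1_position"].astype(int)))
    refs: dict[str, pd.DataFrame] = {}
    for k in range(n_references):
        n_shared = int(round(shared_fraction * len(study)))
        pick = rng.choice(len(study), size=n_shared, replace=False)
        rows = [study[i] for i in sorted(pick)]
        accs = sorted(sites["accession"].unique())
        existing = set(study) | set(rows)
        added = 0
        while added < n_extra:
            acc = accs[int(rng.integers(len(accs)))]
            pos = int(rng.integers(5, 2000))
            if (acc, pos) not in existing:
                rows.append((acc, pos))
                existing.add((acc, pos))
                added += 1
        refs[f"ref{chr(ord('A') + k)}"] = pd.DataFrame(rows, columns=["accession", "p1_position"])
    return refs
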