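"""Seeded synthetic-data generators.

Each generator emulates the statistical structure one pipeline stage assumes
and emits its ground truth alongside the data, so every stage is testable
without downloads:

* genome pairs with programmed SNP rate, inversions, and contig splits, plus
  the match table an aligner would produce (constructed directly, consistent
  with the emitted FASTA by construction);
* additive tree distances with truncated Gaussian noise, including an
  11-taxon preset mirroring the study genus's clade structure (two sister
  species pairs, a distant three-species clade, an outgroup);
* raw GC-TOFMS isotopologue intensities generated from known fluxes under a
  1-13C xylose tracer, convolved with the derivatization-element natural
  abundance of packaged (synthetic, reconstructed) fragment formulas and
  degraded with Gaussian area noise.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .correction import FragmentSpec, correction_matrix
from .emu import TracerSpec, one_13c_xylose, simulate_mdv
from .genome import MATCH_COLUMNS
from .network import (FluxVector, Reaction, ReactionNetwork, Term,
                      load_fixture_model, sample_feasible_flux)
from .phylo import PhyloTree

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genomes

@dataclasses.dataclass
class GenomePairBundle:
    reference: dict[str, str]          # chromosome -> sequence
    contigs: dict[str, str]            # contig -> sequence
    match_table: pd.DataFrame
    truth: pd.DataFrame                # contig, chromosome, start, end, strand, identity
    params: dict


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _mutate(rng: np.random.Generator, seq: str, snp_rate: float) -> tuple[str, int]:
    """Substitute bases at snp_rate; returns mutated sequence and SNP count."""
    arr = np.array(list(seq))
    n_mut = rng.binomial(len(arr), snp_rate)
    if n_mut == 0:
        return seq, 0
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    shift = rng.integers(1, 4, n_mut)
    codes = np.searchsorted(_BASES, arr[pos])
    arr[pos] = _BASES[(codes + shift) % 4]
    return "".join(arr), int(n_mut)


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gen_genome_pair(seed: int = 0, n_chromosomes: int = 4,
                    chrom_length: int = 20000, snp_rate: float = 0.05,
                    n_rearrangements: int = 1,
                    n_contigs: int = 8) -> GenomePairBundle:
    """A reference genome and a derived, mutated, rearranged assembly.

    The derived assembly splits the reference into ``n_contigs`` segments,
    shuffles their naming order, substitutes bases at ``snp_rate`` and
    reverse-complements ``n_rearrangements`` of the segments.  The match
    table contains one match per contig whose identity equals the realized
    substitution fraction of that segment.
    """
    if not 0.0 <= snp_rate <= 0.3:
        raise ValueError("snp_rate must be in [0, 0.3]")
    if n_contigs < n_chromosomes:
        raise ValueError("need at least one contig per chromosome")
    rng = np.random.default_rng(seed)
    reference = {f"chr{i + 1}": _random_seq(rng, chrom_length)
                 for i in range(n_chromosomes)}
    # segment boundaries: distribute contigs over chromosomes round-robin
    segments = []  # (chrom, start, end)
    per_chrom = [n_contigs // n_chromosomes] * n_chromosomes
    for i in range(n_contigs % n_chromosomes):
        per_chrom[i] += 1
    for ci, chrom in enumerate(reference):
        k = per_chrom[ci]
        cuts = np.sort(rng.choice(
            np.arange(1000, chrom_length - 1000), size=k - 1, replace=False)) \
            if k > 1 else np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), chrom_length]
        for s, e in zip(bounds[:-1], bounds[1:]):
            segments.append((chrom, int(s), int(e)))
    if n_rearrangements > len(segments):
        raise ValueError("more rearrangements than segments")
    inverted = set(rng.choice(len(segments), size=n_rearrangements,
                              replace=False).tolist())
    order = rng.permutation(len(segments))
    contigs: dict[str, str] = {}
    rows, truth_rows = [], []
    for rank, seg_idx in enumerate(order, start=1):
        chrom, start, end = segments[seg_idx]
        seq, n_mut = _mutate(rng, reference[chrom][start:end], snp_rate)
        strand = "-" if seg_idx in inverted else "+"
        if strand == "-":
            seq = revcomp(seq)
        name = f"contig{rank}"
        contigs[name] = seq
        identity = 1.0 - n_mut / (end - start)
        rows.append((name, 0, end - start, chrom, start, end, strand,
                     identity, 60))
        truth_rows.append((name, chrom, start, end, strand, identity))
    match_table = pd.DataFrame(rows, columns=MATCH_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=[
        "contig", "chromosome", "start", "end", "strand", "identity"])
    params = dict(seed=seed, n_chromosomes=n_chromosomes,
                  chrom_length=chrom_length, snp_rate=snp_rate,
                  n_rearrangements=n_rearrangements, n_contigs=n_contigs)
    return GenomePairBundle(reference, contigs, match_table, truth, params)


def write_genome_pair(bundle: GenomePairBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kio.write_fasta(bundle.reference, out / "reference.fa")
    kio.write_fasta(bundle.contigs, out / "assembly.fa")
    kio.write_match_table(bundle.match_table, out / "matches.tsv")
    bundle.truth.to_csv(out / "truth.csv", index=False)


# ---------------------------------------------------------------------------
# tree distances

@dataclasses.dataclass
class TreeDistanceBundle:
    distances: pd.DataFrame
    tree: PhyloTree
    params: dict


def _random_tree(rng: np.random.Generator, labels: list[str],
                 length_range: tuple[float, float] = (0.05, 0.3)) -> PhyloTree:
    tree = PhyloTree.star(labels[:3])
    for taxon in labels[3:]:
        edges = list(tree.g.edges)
        tree = tree.attach_leaf(taxon, edges[rng.integers(len(edges))])
    for u, v in tree.g.edges:
        tree.g.edges[u, v]["length"] = float(rng.uniform(*length_range))
    return tree


def gen_tree_distances(seed: int = 0, n_taxa: int = 8,
                       noise_sd: float = 0.0,
                       labels: list[str] | None = None,
                       tree: PhyloTree | None = None) -> TreeDistanceBundle:
    """Additive distances from a random unrooted binary tree plus noise.

    Noise is Gaussian on each pairwise distance, truncated at zero, applied
    symmetrically; noise_sd = 0 gives an exactly additive matrix.
    """
    if n_taxa < 4 and tree is None:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    if tree is None:
        labels = labels or [f"t{i + 1}" for i in range(n_taxa)]
        tree = _random_tree(rng, labels)
    D = tree.path_lengths()
    if noise_sd > 0:
        n = len(D)
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        noise = np.triu(noise, 1)
        noise = noise + noise.T
        D = pd.DataFrame(np.maximum(D.to_numpy() + noise, 0.0),
                         index=D.index, columns=D.columns)
        np.fill_diagonal(D.values, 0.0)
    return TreeDistanceBundle(D, tree, dict(seed=seed, n_taxa=len(D),
                                            noise_sd=noise_sd))


#: 11-taxon preset mirroring the study genus: two close sister-pair clades
#: (phaffii+kurtzmanii vs pastoris+ulmi), a distant three-species clade, and
#: a far outgroup.  Branch lengths are plausible Mash-distance scale.
KOMAGATAELLA_PRESET_NEWICK = (
    "((((phaffii_a:0.002,phaffii_b:0.002):0.02,kurtzmanii:0.03):0.04,"
    "(((pastoris_a:0.001,pastoris_b:0.001):0.002,pastoris_c:0.003):0.025,"
    "ulmi:0.035):0.04):0.06,"
    "((mondaviorum:0.05,populi:0.045):0.02,pseudopastoris:0.06):0.07,"
    "outgroup:0.28);"
)


def komagataella_preset(seed: int = 0, noise_sd: float = 0.002) -> TreeDistanceBundle:
    tree = PhyloTree.from_newick(KOMAGATAELLA_PRESET_NEWICK)
    return gen_tree_distances(seed=seed, noise_sd=noise_sd, tree=tree)


# ---------------------------------------------------------------------------
# 13C labeling datasets

#: Net-flux scenarios on the fixture network (uptake-normalized rates).
FLUX_SCENARIOS: dict[str, dict[str, float]] = {
    "oxppp_zero": {"XYLUP": 1.0, "XOLOUT": 0.1, "G6PDH": 0.0,
                   "G6PASE": 0.05, "BIOMASS": 0.15},
    "baseline": {"XYLUP": 1.0, "XOLOUT": 0.1, "G6PDH": 0.08,
                 "G6PASE": 0.05, "BIOMASS": 0.15},
}

#: Exchange fluxes used when generating ground truth on the fixture network.
DEFAULT_EXCHANGES: dict[str, float] = {
    "RPE": 0.3, "RPI": 0.2, "TKT1": 0.1, "TAL": 0.1, "TKT2": 0.05,
    "PGI": 0.2, "FBA": 0.05, "GAPDH": 0.5, "ENO": 0.5,
}


def load_fragment_specs() -> list[FragmentSpec]:
    """Packaged fragment table (synthetic reconstruction of ethoxime-TMS ions)."""
    ref = importlib.resources.files("komaflux.data") / "fragments_synthetic.csv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p)
    return [FragmentSpec.from_formula(r["metabolite"], r["fragment_formula"],
                                      int(r["n_backbone_carbons"]),
                                      retention_time=float(r["rt"]),
                                      adduct=str(r["adduct"]))
            for _, r in df.iterrows()]


@dataclasses.dataclass
class MfaBundle:
    measurements: list[kio.Measurement]    # raw intensities + SDs
    true_flux: FluxVector
    true_cids: dict[str, np.ndarray]       # backbone MDVs (fractions)
    constraints: dict[str, float]
    tracer: TracerSpec
    params: dict


def gen_mfa_dataset(seed: int = 0, net: ReactionNetwork | None = None,
                    flux_scenario: str | dict[str, float] = "oxppp_zero",
                    tracer: TracerSpec | None = None,
                    noise_sd: float = 0.003,
                    exchanges: dict[str, float] | None = None,
                    fragments: list[FragmentSpec] | None = None,
                    area_scale: float = 1e6) -> MfaBundle:
    """Raw isotopologue measurement set generated from known fluxes.

    Backbone MDVs are simulated from the scenario's feasible flux vector,
    convolved through each fragment's natural-abundance correction matrix,
    scaled to instrument-like areas, and degraded with additive Gaussian
    noise of SD ``noise_sd * area_scale``.
    """
    rng = np.random.default_rng(seed)
    if net is None:
        net = load_fixture_model()
    if isinstance(flux_scenario, str):
        constraints = FLUX_SCENARIOS[flux_scenario]
    else:
        constraints = dict(flux_scenario)
    tracer = tracer or one_13c_xylose()
    exchanges = DEFAULT_EXCHANGES if exchanges is None else exchanges
    fragments = fragments or load_fragment_specs()
    v = sample_feasible_flux(net, constraints=constraints, exchange=exchanges,
                             rng_seed=seed)
    targets = [f.metabolite for f in fragments]
    cids = simulate_mdv(net, v, tracer, targets)
    measurements = []
    for frag in fragments:
        mdv = cids[frag.metabolite]
        M = correction_matrix(frag)
        scale = area_scale * float(rng.uniform(0.5, 2.0))
        raw = M @ (mdv * scale)
        sd_abs = noise_sd * scale
        if noise_sd > 0:
            raw = np.clip(raw + rng.normal(0.0, sd_abs, len(raw)), 0.0, None)
        sds = np.full(len(raw), max(sd_abs, 1e-9 * scale))
        measurements.append(kio.Measurement(frag, raw, sds))
    return MfaBundle(measurements, v, cids, constraints, tracer,
                     dict(seed=seed, scenario=flux_scenario, noise_sd=noise_sd,
                          area_scale=area_scale))


def gen_pascal_qc_sample(seed: int = 0, n_carbons: int = 3,
                         fragment: FragmentSpec | None = None,
                         noise_sd: float = 0.0,
                         area_scale: float = 1e6) -> kio.Measurement:
    """A 50:50 12C/13C reference extract measurement (binomial backbone CID)."""
    from scipy.stats import binom

    rng = np.random.default_rng(seed)
    frag = fragment or FragmentSpec.from_formula(
        "QC", f"C{n_carbons + 9}H32O7PSi3", n_carbons)
    cid = binom.pmf(np.arange(n_carbons + 1), n_carbons, 0.5)
    M = correction_matrix(frag)
    raw = M @ (cid * area_scale)
    if noise_sd > 0:
        raw = np.clip(raw + rng.normal(0, noise_sd * area_scale, len(raw)), 0, None)
    sds = np.full(len(raw), max(noise_sd * area_scale, 1e-3 * area_scale))
    return kio.Measurement(frag, raw, sds)


# ---------------------------------------------------------------------------
# small oracle network

def toy_branch_network() -> ReactionNetwork:
    """A 4-balanced-metabolite network with one reversible step.

    A 3-carbon substrate S either isomerizes directly to the product M
    (reversible) or is decarboxylated to a 2-carbon intermediate D that is
    re-carboxylated from the shared CO2 pool, which is diluted by an external
    natural-abundance CO2 inflow.  The branching ratio is the single free
    net flux once uptake and CO2 inflow are fixed, and it is identifiable
    from the product MDV under a 1-13C substrate tracer.
    """
    t = Term
    rxns = [
        Reaction("UP", [t("S_ext", 1, "abc")], [t("S", 1, "abc")], False),
        Reaction("ISO", [t("S", 1, "abc")], [t("M", 1, "abc")], True),
        Reaction("DC", [t("S", 1, "abc")], [t("D", 1, "bc"), t("CO2", 1, "a")],
                 False),
        Reaction("CX", [t("D", 1, "ab"), t("CO2", 1, "c")], [t("M", 1, "abc")],
                 False),
        Reaction("CIN", [t("CO2in_ext", 1, "a")], [t("CO2", 1, "a")], False),
        Reaction("COUT", [t("CO2", 1, "a")], [t("CO2out_ext", 1, "a")], False),
        Reaction("MOUT", [t("M", 1, "abc")], [t("M_ext", 1, "abc")], False),
    ]
    return ReactionNetwork(rxns)


def toy_branch_tracer(purity: float = 0.99) -> TracerSpec:
    return TracerSpec.positional("S_ext", 3, {1: purity})
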