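"""Shared fixtures: the synthetic study genome and a cached PSE sweep."""

from __future__ import annotations

import random

import pytest

from amplitile import design, fixtures, genome as gmod, pairing, scan, specificity


@pytest.fixture(scope="session")
def fixture_spec():
    return fixtures.FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def study(fixture_spec):
    """Genome + truth table + variant records for the default fixture."""
    genome, truth = fixtures.generate_genome(fixture_spec)
    records = fixtures.generate_variants(fixture_spec, genome, truth)
    return genome, truth, records


@pytest.fixture(scope="session")
def variant_mask(study):
    _genome, _truth, records = study
    mask = gmod.VariantMask()
    for chrom, pos, _ref, _alt, cls in records:
        mask.add(chrom, pos, cls)
    return mask


@pytest.fixture(scope="session")
def target_region(fixture_spec, study, variant_mask):
    genome, _truth, _records = study
    return gmod.extract_masked_region(
        genome,
        fixture_spec.target_chrom,
        fixture_spec.target_start,
        fixture_spec.target_stop,
        mask=variant_mask,
    )


@pytest.fixture(scope="session")
def uod_result(target_region, study):
    genome, _truth, _records = study
    return design.run_uod(target_region, genome)


@pytest.fixture(scope="session")
def kmer_index(study):
    genome, _truth, _records = study
    return scan.KmerIndex(genome, 7)


@pytest.fixture(scope="session")
def pse_sweep(uod_result, study, kmer_index):
    """Hits, thermoalignments and misprime profiles for every UOD candidate."""
    genome, _truth, _records = study
    hits: dict[str, list[scan.LocalHit]] = {}
    tas: dict[str, list[specificity.ThermoAlignment]] = {}
    profiles: dict[str, specificity.MisprimeProfile] = {}
    for oligo in uod_result.passing:
        ohits = scan.find_local_hits(oligo, genome, scan.ScanParams(), kmer_index)
        hits[oligo.id] = ohits
        otas = []
        for h in ohits:
            ta = specificity.build_thermoalignment(h, oligo, genome)
            if ta is not None:
                specificity.misprime_tm(ta)
                otas.append(ta)
        tas[oligo.id] = otas
        prof = specificity.misprime_profile(oligo, otas)
        specificity.specificity_filter(prof)
        profiles[oligo.id] = prof
    return hits, tas, profiles


@pytest.fixture(scope="session")
def specific_candidates(uod_result, pse_sweep):
    _hits, _tas, profiles = pse_sweep
    return [o for o in uod_result.passing if profiles[o.id].pass_specificity]


@pytest.fixture(scope="session")
def study_pairs(specific_candidates, pse_sweep, target_region):
    _hits, _tas, profiles = pse_sweep
    return pairing.enumerate_pairs(
        specific_candidates,
        profiles,
        target_region,
        pairing.PPSSettings(amplicon_len_min=300, amplicon_len_max=1500),
    )


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
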