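"""Synthetic-data generator: construction guarantees and determinism."""

import pytest

from grainrisk.fate import Fate
from grainrisk.models import Disease, GrainRiskError, ProteinClass, Stage
from grainrisk.synthetic_data import (
    DEFAULT_GD_SURVIVAL,
    NoiseConfig,
    StudyConfig,
    SyntheticConfig,
    default_study_config,
    make_fraction_pools,
    make_proteome,
    make_study,
)


def single_epitope_config(seed=5, survival=1.0, **kwargs):
    return SyntheticConfig(
        rng_seed=seed,
        n_proteins_per_class={ProteinClass.ALPHA_GLIADIN: 1},
        protein_length_range=(80, 120),
        implanted_epitopes=(("93", ProteinClass.ALPHA_GLIADIN, 1),),
        gd_survival={c: survival for c in ProteinClass},
        **kwargs,
    )


class TestMakeProteome:
    def test_implant_present_at_registered_offset(self, cd_epitopes):
        proteome, registry = make_proteome(single_epitope_config(), cd_epitopes)
        assert len(proteome) == 1 and len(registry) == 1
        imp = registry[0]
        seq = proteome[0].sequence
        assert seq[imp.start - 1 : imp.end] == "FRPQQPYPQ"
        assert seq.count("FRPQQPYPQ") == 1

    def test_same_seed_reproduces_proteome(self, cd_epitopes):
        a, _ = make_proteome(single_epitope_config(), cd_epitopes)
        b, _ = make_proteome(single_epitope_config(), cd_epitopes)
        assert [p.sequence for p in a] == [p.sequence for p in b]

    def test_different_seed_changes_background(self, cd_epitopes):
        a, _ = make_proteome(single_epitope_config(seed=5), cd_epitopes)
        b, _ = make_proteome(single_epitope_config(seed=6), cd_epitopes)
        assert [p.sequence for p in a] != [p.sequence for p in b]

    def test_zero_proteins_gives_empty_proteome(self, cd_epitopes):
        cfg = SyntheticConfig(
            n_proteins_per_class={}, implanted_epitopes=()
        )
        proteome, registry = make_proteome(cfg, cd_epitopes)
        assert proteome == [] and registry == []

    def test_epitope_longer_than_protein_is_config_error(self, cd_epitopes):
        cfg = SyntheticConfig(
            n_proteins_per_class={ProteinClass.ALPHA_GLIADIN: 1},
            protein_length_range=(6, 8),
            implanted_epitopes=(("93", ProteinClass.ALPHA_GLIADIN, 1),),
        )
        with pytest.raises(GrainRiskError):
            make_proteome(cfg, cd_epitopes)

    def test_descriptions_round_trip_through_attribution(self):
        cfg = SyntheticConfig(implanted_epitopes=())
        proteome, _ = make_proteome(cfg)
        for prot in proteome:
            from grainrisk.models import attribute_protein_class

            assert attribute_protein_class(prot.description) is prot.protein_class

    def test_invalid_probability_rejected(self):
        with pytest.raises(GrainRiskError):
            SyntheticConfig(gd_survival={ProteinClass.ATI: 1.5})


class TestFractionPools:
    def test_forced_survival_yields_intact_gd_window(self, cd_epitopes):
        cfg = single_epitope_config(survival=1.0)
        proteome, registry = make_proteome(cfg, cd_epitopes)
        pools = make_fraction_pools(proteome, registry, cfg, "S", cd_epitopes)
        gd = [p.sequence for p in pools.gd_rows()]
        assert any("FRPQQPYPQ" in s for s in gd)
        assert pools.implant_survived == [True]

    def test_forced_degradation_leaves_no_intact_gd_epitope(self, cd_epitopes):
        cfg = single_epitope_config(survival=0.0)
        proteome, registry = make_proteome(cfg, cd_epitopes)
        pools = make_fraction_pools(proteome, registry, cfg, "S", cd_epitopes)
        gd = [p.sequence for p in pools.gd_rows()]
        assert gd, "a degradation fragment should be emitted"
        assert all("FRPQQPYPQ" not in s for s in gd)

    def test_degraded_fragments_can_be_disabled(self, cd_epitopes):
        cfg = single_epitope_config(survival=0.0, degraded_emit_fragments=False)
        proteome, registry = make_proteome(cfg, cd_epitopes)
        pools = make_fraction_pools(proteome, registry, cfg, "S", cd_epitopes)
        assert pools.gd_rows() == []

    def test_gliadin_peptides_go_to_f2(self, cd_epitopes):
        cfg = single_epitope_config()
        proteome, registry = make_proteome(cfg, cd_epitopes)
        pools = make_fraction_pools(proteome, registry, cfg, "S", cd_epitopes)
        assert pools.pools[Stage.F1] == [] and pools.pools[Stage.F3] == []
        assert pools.pools[Stage.F2]

    def test_decoys_contain_no_fixture_epitope(self, cd_epitopes, wa_epitopes):
        cfg = SyntheticConfig(
            rng_seed=3,
            n_proteins_per_class={ProteinClass.GAMMA_GLIADIN: 1},
            protein_length_range=(60, 80),
            implanted_epitopes=(),
            noise=NoiseConfig(decoy_count=50),
        )
        proteome, registry = make_proteome(cfg)
        pools = make_fraction_pools(proteome, registry, cfg, "S")
        all_epitopes = cd_epitopes + wa_epitopes
        decoys = [p for p in pools.gd_rows()]
        assert len(decoys) == 50
        for row in decoys:
            assert not any(e.sequence in row.sequence for e in all_epitopes)


class TestMakeStudy:
    def test_identical_configs_make_everything_conserved(self):
        cfg = SyntheticConfig(
            rng_seed=4,
            gd_survival={c: 1.0 for c in ProteinClass},
        )
        study = StudyConfig(samples=(("REF", cfg), ("1", cfg), ("2", cfg)))
        ds = make_study(study)
        for disease in Disease:
            for vec in ds.ledger.presence[disease].values():
                assert all(vec)

    def test_reference_only_implant_is_differential(self, cd_epitopes, wa_epitopes):
        surv = {c: 1.0 for c in ProteinClass}
        ref = SyntheticConfig(
            rng_seed=4,
            n_proteins_per_class={ProteinClass.ALPHA_GLIADIN: 1},
            implanted_epitopes=(("93", ProteinClass.ALPHA_GLIADIN, 1),),
            gd_survival=surv,
        )
        geno = SyntheticConfig(
            rng_seed=5,
            n_proteins_per_class={ProteinClass.ALPHA_GLIADIN: 1},
            implanted_epitopes=(),
            gd_survival=surv,
        )
        ds = make_study(StudyConfig(samples=(("REF", ref), ("1", geno))))
        assert ds.ledger.presence[Disease.CD]["93"] == (True, False)
        assert ds.ledger.per_sample["1"].fates[Disease.CD]["93"] is Fate.NOT_EXPRESSED

    def test_study_needs_two_samples(self):
        with pytest.raises(GrainRiskError):
            StudyConfig(samples=(("REF", SyntheticConfig()),))

    def test_default_study_is_deterministic(self):
        a = make_study(default_study_config(2, n_genotypes=2))
        b = make_study(default_study_config(2, n_genotypes=2))
        assert a.samples == b.samples
        for sid in a.samples:
            assert [p.sequence for p in a.pools[sid].gd_rows()] == [
                p.sequence for p in b.pools[sid].gd_rows()
            ]
        assert a.ledger.presence == b.ledger.presence

    def test_survival_defaults_cover_every_class(self):
        assert set(DEFAULT_GD_SURVIVAL) == set(ProteinClass)
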