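"""Synthetic pangenome generator: determinism, planted structure, identity control."""

from __future__ import annotations

import numpy as np
import pytest

from panstrep import (
    AnnotationLabel,
    SyntheticPangenomeSpec,
    generate_annotations,
    generate_pangenome,
    mutate_sequence,
    write_pangenome,
)
from panstrep.errors import ConfigurationError

from oracles import pairwise_identity


def _flat(proteomes):
    return [r for g in sorted(proteomes) for r in proteomes[g]]


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_genomes": 1}, "n_genomes"),
            ({"within_group_identity": 0.0}, "within_group_identity"),
            ({"within_group_identity": 1.5}, "within_group_identity"),
            ({"paralog_rate": -0.1}, "paralog_rate"),
            ({"n_unique_per_genome": -1}, "n_unique_per_genome"),
            ({"protein_length_range": (0, 10)}, "protein_length_range"),
            ({"accessory_prevalence_weights": {(0.0, 0.5): 3}}, "accessory_prevalence_weights"),
        ],
    )
    def test_invalid_field_named_in_error(self, kwargs, field):
        spec = SyntheticPangenomeSpec(**kwargs)
        with pytest.raises(ConfigurationError, match=field):
            spec.validate()


class TestGeneratePangenome:
    def test_identity_copies(self):
        # 3 genomes x 5 core groups at identity 1.0: 15 identical-copy proteins
        spec = SyntheticPangenomeSpec(
            n_genomes=3,
            n_core_groups=5,
            accessory_prevalence_weights={},
            n_unique_per_genome=0,
            paralog_rate=0.0,
            within_group_identity=1.0,
            seed=1,
        )
        proteomes, truth = generate_pangenome(spec)
        records = _flat(proteomes)
        assert len(records) == 15
        assert len(truth.group_genomes) == 5
        for genomes in truth.group_genomes.values():
            assert len(genomes) == 3
        by_group: dict[str, set[str]] = {}
        for r in records:
            by_group.setdefault(truth.protein_to_group[r.protein_id], set()).add(r.sequence)
        # identity 1.0 means every member is an exact ancestor copy
        assert all(len(seqs) == 1 for seqs in by_group.values())

    def test_seed_determinism_bytes(self, tmp_path):
        spec = SyntheticPangenomeSpec(
            n_genomes=3, n_core_groups=4, n_unique_per_genome=2, seed=7
        )
        for out in (tmp_path / "a", tmp_path / "b"):
            proteomes, truth = generate_pangenome(spec)
            write_pangenome(proteomes, truth, spec, out)
        for name in sorted(p.name for p in (tmp_path / "a").iterdir()):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_within_group_identity_measured_by_dp_oracle(self):
        spec = SyntheticPangenomeSpec(
            n_genomes=6,
            n_core_groups=8,
            accessory_prevalence_weights={},
            n_unique_per_genome=0,
            paralog_rate=0.0,
            within_group_identity=0.9,
            seed=42,
        )
        proteomes, truth = generate_pangenome(spec)
        seqs = {r.protein_id: r.sequence for r in _flat(proteomes)}
        by_group: dict[str, list[str]] = {}
        for pid, gid in truth.protein_to_group.items():
            by_group.setdefault(gid, []).append(pid)
        identities = []
        for members in by_group.values():
            members.sort()
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    identities.append(
                        pairwise_identity(seqs[members[i]], seqs[members[j]])
                    )
        assert abs(np.mean(identities) - 0.9) < 0.05

    def test_prevalence_bookkeeping(self):
        spec = SyntheticPangenomeSpec(
            n_genomes=8,
            n_core_groups=5,
            accessory_prevalence_weights={(0.2, 0.8): 6},
            n_unique_per_genome=2,
            seed=3,
        )
        proteomes, truth = generate_pangenome(spec)
        recomputed: dict[str, set[str]] = {}
        for r in _flat(proteomes):
            gid = truth.protein_to_group[r.protein_id]
            recomputed.setdefault(gid, set()).add(r.genome_id)
        assert {g: frozenset(v) for g, v in recomputed.items()} == dict(
            truth.group_genomes
        )
        # every generated protein appears exactly once
        assert sorted(r.protein_id for r in _flat(proteomes)) == sorted(
            truth.protein_to_group
        )

    def test_paralogs_are_extra_same_genome_copies(self):
        spec = SyntheticPangenomeSpec(
            n_genomes=4,
            n_core_groups=30,
            accessory_prevalence_weights={},
            n_unique_per_genome=0,
            paralog_rate=0.5,
            seed=9,
        )
        proteomes, truth = generate_pangenome(spec)
        n = len(_flat(proteomes))
        assert n > 4 * 30  # paralog duplicates present
        assert len(truth.group_genomes) == 30


class TestMutateSequence:
    def test_identity_one_is_noop(self):
        rng = np.random.default_rng(0)
        assert mutate_sequence("ACDEFGHIKL", 1.0, rng) == "ACDEFGHIKL"

    def test_substitution_count_matches_contract(self):
        rng = np.random.default_rng(0)
        child = mutate_sequence("ACDEFGHIKL", 0.8, rng)
        assert len(child) == 10
        assert sum(a != b for a, b in zip("ACDEFGHIKL", child)) == 2

    def test_target_identity_recovered_by_dp_oracle(self):
        rng = np.random.default_rng(1)
        parent = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(20, size=100)
        )
        child = mutate_sequence(parent, 0.5, rng)
        # substitution-only mutation: the global alignment is the
        # position-by-position comparison of the equal-length strings
        global_identity = sum(a == b for a, b in zip(parent, child)) / len(parent)
        assert global_identity == pytest.approx(0.5, abs=0.02)

    def test_empty_parent_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mutate_sequence("", 0.9, np.random.default_rng(0))


class TestGenerateAnnotations:
    def _truth(self):
        spec = SyntheticPangenomeSpec(
            n_genomes=3,
            n_core_groups=2,
            accessory_prevalence_weights={},
            n_unique_per_genome=1,
            paralog_rate=0.0,
            seed=2,
        )
        return generate_pangenome(spec)

    def test_domain_label_reaches_every_member(self):
        _, truth = self._truth()
        tables = generate_annotations(
            truth, {"T00001": [AnnotationLabel("domains", "PF03777")]}
        )
        members = {p for p, g in truth.protein_to_group.items() if g == "T00001"}
        assert set(tables["domains"]["protein_id"]) == members
        assert (tables["domains"]["accession"] == "PF03777").all()

    def test_ko_scores_straddle_relaxed_threshold(self):
        _, truth = self._truth()
        tables = generate_annotations(
            truth,
            {
                "T00001": [
                    AnnotationLabel("ko", "K00001", evalue=1e-90, score=10.0, threshold=50.0)
                ],
                "T00002": [
                    AnnotationLabel("ko", "K00002", evalue=1e-70, score=10.0, threshold=50.0)
                ],
            },
        )
        evs = set(tables["ko"]["ievalue"])
        assert {1e-90, 1e-70} == evs  # both sides of the 1e-80 rescue rule

    def test_empty_profile_gives_header_only_tables(self):
        _, truth = self._truth()
        tables = generate_annotations(truth, {})
        assert all(df.empty for df in tables.values())
        assert list(tables["cog"].columns) == ["protein_id", "cog_category", "evalue"]

    def test_unknown_group_rejected(self):
        _, truth = self._truth()
        with pytest.raises(ConfigurationError, match="ZZZ"):
            generate_annotations(truth, {"ZZZ": [AnnotationLabel("cog", "K")]})
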