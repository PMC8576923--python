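"""Plugin discovery, selection, compatibility, invocation, score checks."""

import pandas as pd
import pytest
import yaml

from priobench.core_data import strip_classification
from priobench.errors import (
    CompatibilityError,
    ManifestError,
    PluginCrashError,
    ContainerError,
    ScoreValidationError,
    SelectionError,
)
from priobench.fixtures import (
    Constant,
    CrashOn,
    DatasetSpec,
    MockPluginSpec,
    Noisy,
    PerfectOracle,
    StubContainerRunner,
    generate_dataset,
    materialize_container_stub,
    materialize_mock_plugin,
)
from priobench.plugins import (
    ScoredVariant,
    check_compatibility,
    discover_plugins,
    invoke_container,
    invoke_in_process,
    run_plugins,
    select_plugins,
    validate_scores,
)

MANIFEST = {
    "manifest-version": 1,
    "name": "demo",
    "version": "1.0",
    "supported-variation-types": ["SNP"],
    "cutoff": 0.5,
    "reference-genome": "GRCh37",
    "entry-point": {"mode": "python", "file": "score.py"},
}


def write_plugin_dir(root, name, manifest_patch=None):
    d = root / name
    d.mkdir(parents=True)
    manifest = dict(MANIFEST, name=name)
    manifest.update(manifest_patch or {})
    (d / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    (d / "score.py").write_text(
        "def process(variants):\n"
        "    return [(int(u), 0.9) for u in variants['UID']]\n"
    )
    return d


class TestDiscovery:
    def test_counts_only_manifest_dirs(self, tmp_path):
        write_plugin_dir(tmp_path, "a")
        write_plugin_dir(tmp_path, "b")
        (tmp_path / "README.txt").write_text("not a plugin")
        (tmp_path / "empty").mkdir()
        plugins = discover_plugins(tmp_path)
        assert [p.name for p in plugins] == ["a", "b"]

    def test_empty_dir(self, tmp_path):
        assert discover_plugins(tmp_path) == []

    def test_deterministic_order(self, tmp_path):
        for name in ["zeta", "alpha", "mid"]:
            write_plugin_dir(tmp_path, name)
        once = [p.name for p in discover_plugins(tmp_path)]
        again = [p.name for p in discover_plugins(tmp_path)]
        assert once == again == ["alpha", "mid", "zeta"]

    def test_missing_required_field_aborts(self, tmp_path):
        d = write_plugin_dir(tmp_path, "broken")
        manifest = dict(MANIFEST, name="broken")
        del manifest["cutoff"]
        (d / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        with pytest.raises(ManifestError, match="cutoff"):
            discover_plugins(tmp_path)

    def test_manifest_in_root_itself(self, tmp_path):
        (tmp_path / "manifest.yaml").write_text(yaml.safe_dump(MANIFEST))
        (tmp_path / "score.py").write_text("def process(v): return []\n")
        assert [p.root for p in discover_plugins(tmp_path)] == [tmp_path]


class TestSelection:
    def test_always_true_selects_all(self, tmp_path):
        for name in ["a", "b", "c"]:
            write_plugin_dir(tmp_path, name)
        plugins = discover_plugins(tmp_path)
        assert select_plugins(plugins, lambda m: True) == plugins

    def test_no_match_raises(self, tmp_path):
        write_plugin_dir(tmp_path, "a")
        plugins = discover_plugins(tmp_path)
        with pytest.raises(SelectionError):
            select_plugins(plugins, lambda m: m.name == "X")

    def test_predicate_over_supported_types(self, tmp_path):
        write_plugin_dir(tmp_path, "snp_only")
        write_plugin_dir(tmp_path, "both",
                         {"supported-variation-types": ["SNP", "INDEL"]})
        write_plugin_dir(tmp_path, "indel_only",
                         {"supported-variation-types": ["INDEL"]})
        plugins = discover_plugins(tmp_path)
        selected = select_plugins(
            plugins, lambda m: "SNP" in m.supported_variation_types
        )
        expected = [p for p in plugins
                    if "SNP" in p.manifest.supported_variation_types]
        assert selected == expected


class TestCompatibility:
    def test_snp_only_plugin_rejects_indel_data(self, tmp_path, dataset_mixed):
        data, _ = dataset_mixed
        write_plugin_dir(tmp_path, "snp_only")
        plugins = discover_plugins(tmp_path)
        report = check_compatibility(plugins, strip_classification(data))
        assert not report.ok
        assert report.failures[0].dimension == "variation_type"
        with pytest.raises(CompatibilityError):
            report.raise_if_failed()

    def test_genome_alias_resolves(self, tmp_path):
        data, _ = generate_dataset(DatasetSpec(5, 5, seed=2, rg="hg19"))
        write_plugin_dir(tmp_path, "grch37",
                         {"reference-genome": "GRCh37"})
        plugins = discover_plugins(tmp_path)
        assert check_compatibility(plugins, strip_classification(data)).ok

    def test_matching_types_and_genome_pass(self, tmp_path, dataset_100):
        data, _ = dataset_100
        write_plugin_dir(tmp_path, "ok")
        plugins = discover_plugins(tmp_path)
        assert check_compatibility(plugins, strip_classification(data)).ok

    def test_genome_mismatch_reported(self, tmp_path, dataset_100):
        data, _ = dataset_100
        write_plugin_dir(tmp_path, "hg38_only", {"reference-genome": "hg38"})
        plugins = discover_plugins(tmp_path)
        report = check_compatibility(plugins, strip_classification(data))
        assert [f.dimension for f in report.failures] == ["reference_genome"]


class TestValidateScores:
    def make_variants(self, dataset_100):
        data, _ = dataset_100
        return strip_classification(data)

    def test_complete_scores_pass(self, dataset_100):
        variants = self.make_variants(dataset_100)
        scores = [ScoredVariant(u, 0.5) for u in variants.uids]
        assert validate_scores(variants, scores) == scores

    def test_missing_uid_listed(self, dataset_100):
        variants = self.make_variants(dataset_100)
        scores = [ScoredVariant(u, 0.5) for u in variants.uids[:-1]]
        with pytest.raises(ScoreValidationError) as err:
            validate_scores(variants, scores)
        assert err.value.missing == [variants.uids[-1]]

    def test_nan_score_listed_as_non_finite(self, dataset_100):
        variants = self.make_variants(dataset_100)
        scores = [ScoredVariant(u, 0.5) for u in variants.uids]
        scores[3] = ScoredVariant(scores[3].uid, float("nan"))
        with pytest.raises(ScoreValidationError) as err:
            validate_scores(variants, scores)
        assert err.value.non_finite == [scores[3].uid]

    def test_duplicate_and_unknown_uids_listed(self, dataset_100):
        variants = self.make_variants(dataset_100)
        scores = [ScoredVariant(u, 0.5) for u in variants.uids]
        scores.append(ScoredVariant(variants.uids[0], 0.7))
        scores.append(ScoredVariant(10_000, 0.7))
        with pytest.raises(ScoreValidationError) as err:
            validate_scores(variants, scores)
        assert err.value.duplicated == [variants.uids[0]]
        assert err.value.unknown == [10_000]


class TestInProcessInvocation:
    def test_constant_plugin(self, tmp_path, dataset_100):
        data, _ = dataset_100
        plugin = materialize_mock_plugin(
            MockPluginSpec("const", Constant(0.9)), data, tmp_path / "const"
        )
        scores = invoke_in_process(plugin, strip_classification(data))
        assert len(scores) == len(data)
        assert {sv.score for sv in scores} == {0.9}

    def test_crash_names_plugin(self, tmp_path, dataset_100):
        data, _ = dataset_100
        plugin = materialize_mock_plugin(
            MockPluginSpec("crasher", CrashOn(uid=3)), data, tmp_path / "crash"
        )
        with pytest.raises(PluginCrashError, match="crasher"):
            invoke_in_process(plugin, strip_classification(data))

    def test_oracle_plugin_matches_truth(self, tmp_path, dataset_100):
        data, _ = dataset_100
        plugin = materialize_mock_plugin(
            MockPluginSpec("oracle", PerfectOracle()), data, tmp_path / "oracle"
        )
        scores = {sv.uid: sv.score
                  for sv in invoke_in_process(plugin, strip_classification(data))}
        for entry in data.entries():
            assert (scores[entry.uid] >= 0.5) == (entry.cls == "pathogenic")


class TestContainerContract:
    def test_stub_round_trip(self, tmp_path, dataset_100):
        data, _ = dataset_100
        plugin = materialize_container_stub(
            MockPluginSpec("stub", Constant(0.9)), data, tmp_path / "stub"
        )
        scores = invoke_container(
            plugin, strip_classification(data),
            workdir=tmp_path / "work", runner=StubContainerRunner(),
        )
        assert len(scores) == len(data)
        assert {sv.score for sv in scores} == {0.9}

    def test_missing_output_is_container_error(self, tmp_path, dataset_100):
        data, _ = dataset_100
        plugin = materialize_container_stub(
            MockPluginSpec("silent", Constant(0.9)), data, tmp_path / "silent"
        )
        (plugin.root / "stub.py").write_text(
            "def run(input_path, output_path):\n    pass\n"
        )
        with pytest.raises(ContainerError):
            invoke_container(plugin, strip_classification(data),
                             workdir=tmp_path / "work",
                             runner=StubContainerRunner())

    def test_input_serialization_round_trips(self, tmp_path, dataset_100):
        from priobench.extractors import CsvColumnMap, extract_from_csv

        data, _ = dataset_100
        variants = strip_classification(data)
        plugin = materialize_container_stub(
            MockPluginSpec("ser", Constant(0.5)), data, tmp_path / "ser"
        )
        invoke_container(plugin, variants, workdir=tmp_path / "work",
                         runner=StubContainerRunner())
        written = tmp_path / "work" / "input.csv"
        frame = pd.read_csv(written, dtype=str)
        assert list(frame.columns) == list(variants.table.columns)
        assert len(frame) == len(variants)
        assert [int(u) for u in frame["UID"]] == variants.uids

    def test_reversed_output_order_joins_identically(self, tmp_path, dataset_100):
        data, _ = dataset_100
        variants = strip_classification(data)
        forward = materialize_container_stub(
            MockPluginSpec("fwd", Noisy(1.0, seed=4)), data, tmp_path / "fwd"
        )
        backward = materialize_container_stub(
            MockPluginSpec("fwd", Noisy(1.0, seed=4), reverse_output=True),
            data, tmp_path / "bwd",
        )
        t1, _ = run_plugins([forward], variants, runner=StubContainerRunner(),
                            workdir=tmp_path / "w1")
        t2, _ = run_plugins([backward], variants, runner=StubContainerRunner(),
                            workdir=tmp_path / "w2")
        pd.testing.assert_frame_equal(t1, t2)

    def test_omitted_uid_fails_score_validation(self, tmp_path, dataset_100):
        data, _ = dataset_100
        variants = strip_classification(data)
        plugin = materialize_container_stub(
            MockPluginSpec("omit", Constant(0.9), omit_uid=5),
            data, tmp_path / "omit",
        )
        with pytest.raises(ScoreValidationError) as err:
            run_plugins([plugin], variants, runner=StubContainerRunner(),
                        workdir=tmp_path / "w")
        assert err.value.missing == [5]


class TestRunPlugins:
    def make_plugins(self, tmp_path, data, n=3):
        return [
            materialize_mock_plugin(
                MockPluginSpec(f"m{i}", Noisy(1.0 + i, seed=i)),
                data, tmp_path / f"m{i}",
            )
            for i in range(n)
        ]

    def test_annotation_columns_named_by_manifest(self, tmp_path, dataset_100):
        data, _ = dataset_100
        plugins = self.make_plugins(tmp_path, data, 2)
        table, failed = run_plugins(plugins, strip_classification(data))
        assert failed == []
        assert [c for c in table.columns if c.startswith("m")] == [
            "m0-1.0", "m1-1.0"
        ]

    def test_parallel_equals_serial(self, tmp_path, dataset_100):
        data, _ = dataset_100
        plugins = self.make_plugins(tmp_path, data, 5)
        variants = strip_classification(data)
        serial, _ = run_plugins(plugins, variants, jobs=1)
        parallel, _ = run_plugins(plugins, variants, jobs=4)
        pd.testing.assert_frame_equal(serial, parallel)

    def test_input_not_mutated(self, tmp_path, dataset_100):
        data, _ = dataset_100
        variants = strip_classification(data)
        before = variants.table.copy(deep=True)
        run_plugins(self.make_plugins(tmp_path, data, 2), variants, jobs=2)
        pd.testing.assert_frame_equal(variants.table, before)

    def test_empty_variant_data_is_an_error(self, tmp_path, dataset_100):
        data, _ = dataset_100
        plugins = self.make_plugins(tmp_path, data, 1)
        empty = strip_classification(data)
        empty.table = empty.table.iloc[0:0]
        with pytest.raises(ValueError):
            run_plugins(plugins, empty)

    def test_crash_aborts_and_names_the_plugin(self, tmp_path, dataset_100):
        data, _ = dataset_100
        plugins = self.make_plugins(tmp_path, data, 2)
        plugins.append(materialize_mock_plugin(
            MockPluginSpec("bad", CrashOn(uid=0)), data, tmp_path / "bad"
        ))
        with pytest.raises(PluginCrashError) as err:
            run_plugins(plugins, strip_classification(data), jobs=2)
        notes = "".join(getattr(err.value, "__notes__", []))
        assert "bad-1.0" in notes
        assert "m0-1.0" not in notes

    def test_keep_going_drops_failed_column(self, tmp_path, dataset_100):
        data, _ = dataset_100
        plugins = self.make_plugins(tmp_path, data, 1)
        plugins.append(materialize_mock_plugin(
            MockPluginSpec("bad", CrashOn(uid=0)), data, tmp_path / "bad"
        ))
        table, failed = run_plugins(
            plugins, strip_classification(data), keep_going=True
        )
        assert failed == ["bad-1.0"]
        assert "bad-1.0" not in table.columns
        assert "m0-1.0" in table.columns
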