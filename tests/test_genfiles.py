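"""Output emission: Dockerfiles, run scripts, merge, assembly, scanner."""

import os

import pytest

from imageforge.capture import capture_install
from imageforge.core import BuildPlan, LayerConfig, PackageRequest
from imageforge.errors import DockerfileParseError, ForgeError, PlanValidationError
from imageforge.fixtures import (
    MockSandboxBackend,
    build_mock_registry,
    random_registry_spec,
)
from imageforge.genfiles import (
    GUI_PORT,
    assemble_output_folder,
    build_layer_output,
    build_plan_outputs,
    generate_dockerfile,
    generate_run_scripts,
    merge_layer0_outputs,
    scan_offline_closure,
)


def _layer0_output(registry, requests, image_name="credimage", language="python-stack"):
    backend = MockSandboxBackend(registry)
    manifest, files = capture_install(requests, backend, registry)
    layer = LayerConfig(0, options={"language": language})
    return build_layer_output(layer, manifest, files, image_name=image_name)


@pytest.fixture
def out0(diamond_registry, request_a):
    return _layer0_output(diamond_registry, request_a)


class TestScanner:
    def test_url_fetch_flagged_with_line_number(self):
        text = "FROM ubuntu@sha256:abc\nRUN wget https://example.org/tool.tar.gz\n"
        violations = scan_offline_closure(text)
        assert violations and violations[0].line == 2

    @pytest.mark.parametrize(
        "instruction",
        [
            "RUN apt-get update",
            "RUN apt-get install -y bwa",
            "RUN pip install numpy",
            "RUN conda install -c bioconda samtools",
            'RUN R -e "install.packages(\'ggplot2\')"',
            "RUN git clone git://host/repo",
            "RUN curl -O http://host/file",
        ],
    )
    def test_network_verbs_flagged(self, instruction):
        assert scan_offline_closure(f"FROM ubuntu@sha256:abc\n{instruction}\n")

    @pytest.mark.parametrize(
        "instruction",
        [
            "RUN python -m pip install --no-index --no-deps ./artifacts/a.whl",
            "RUN conda create --offline --yes --prefix /snowflakes/env",
            "RUN dpkg -i ./artifacts/b.deb",
            "RUN R CMD INSTALL ./artifacts/c.tar.gz",
        ],
    )
    def test_offline_forms_pass(self, instruction):
        assert scan_offline_closure(f"FROM ubuntu@sha256:abc\n{instruction}\n") == []

    def test_base_image_line_is_the_permitted_remote_reference(self):
        assert scan_offline_closure("FROM ubuntu@sha256:abc\n") == []

    def test_second_from_is_scanned(self):
        text = "FROM ubuntu@sha256:abc\nFROM other:latest\nRUN wget http://x\n"
        violations = scan_offline_closure(text)
        assert violations and all(v.line == 3 for v in violations)  # FROM lines clean

    def test_unparseable_text_rejected(self):
        with pytest.raises(DockerfileParseError):
            scan_offline_closure("FROM x\nthis is not an instruction\n")
        with pytest.raises(DockerfileParseError):
            scan_offline_closure("RUN echo no-from\n")

    def test_continuation_lines_joined(self):
        text = "FROM x@sha256:abc\nRUN echo a \\\n  && wget http://host/f\n"
        violations = scan_offline_closure(text)
        assert violations and violations[0].line == 2


class TestGenerateDockerfile:
    def test_layer0_offline_closed_and_references_all_volumes(self, out0):
        text = out0.dockerfile_text
        assert scan_offline_closure(text) == []
        assert text.startswith("FROM " + out0.manifest.base_image_ref)
        for vol in out0.chunkset.volumes:
            assert vol.filename in text

    def test_layer2_exposes_gui_port(self, diamond_registry, request_a):
        backend = MockSandboxBackend(diamond_registry)
        manifest, files = capture_install(request_a, backend, diamond_registry)
        layer2 = LayerConfig(2, options={"gui": "rstudio"})
        out = build_layer_output(
            layer2, manifest, files, image_name="credimage", parent_image="credimage:layer1"
        )
        assert f"EXPOSE {GUI_PORT}" in out.dockerfile_text
        assert "8888" in out.dockerfile_text
        assert out.dockerfile_text.startswith("FROM credimage:layer1")

    def test_layer2_multiple_gui_rejected(self, out0):
        layer2 = LayerConfig(2, slug="GUI", options={"gui": "rstudio,jupyterlab"})
        with pytest.raises(ForgeError):
            generate_dockerfile(layer2, out0.manifest, out0.chunk_groups)

    def test_layer2_missing_gui_rejected(self, out0):
        with pytest.raises(ForgeError):
            generate_dockerfile(LayerConfig(2, slug="GUI"), out0.manifest, out0.chunk_groups)

    def test_layer3_nested_runtime_steps(self, out0):
        layer3 = LayerConfig(3, options={"vm": "singularity"})
        text = generate_dockerfile(layer3, out0.manifest, out0.chunk_groups,
                                   parent_image="credimage:layer2")
        assert "singularity" in text.lower()
        assert scan_offline_closure(text) == []


class TestRunScripts:
    def test_layer2_script_pins_platform_port_and_mount(self):
        layer2 = LayerConfig(2, options={"gui": "jupyterlab"})
        posix, win = generate_run_scripts(layer2, "credimage", "/data/shared")
        for script in (posix, win):
            assert "--platform linux/amd64" in script
            assert "/sharedFolder" in script
            assert "8888" in script
        assert "-it" not in posix  # detached, no shell

    def test_layer0_script_attaches_shell_without_ports(self):
        layer0 = LayerConfig(0, options={"language": "python-stack"})
        posix, _ = generate_run_scripts(layer0, "credimage", "/data/shared")
        assert "-it" in posix and "bash" in posix
        assert "-p " not in posix and "8888" not in posix

    def test_dialects_agree_on_image_and_mount(self):
        layer1 = LayerConfig(1)
        posix, win = generate_run_scripts(layer1, "credimage", "/data/shared")
        assert "credimage:layer1" in posix and "credimage:layer1" in win
        assert "/sharedFolder" in posix and "/sharedFolder" in win

    def test_invalid_image_name_rejected(self):
        with pytest.raises(ForgeError):
            generate_run_scripts(LayerConfig(1), "Bad2Name", "/data/shared")


class TestMerge:
    def _two_stacks(self):
        reg_py = build_mock_registry(random_registry_spec(seed=21, n_packages=4))
        reg_r = build_mock_registry(
            random_registry_spec(seed=22, n_packages=3, ecosystem="cran-like")
        )
        reqs_py = [PackageRequest(e.name, e.ecosystem) for e in reg_py.spec.packages]
        reqs_r = [PackageRequest(e.name, e.ecosystem) for e in reg_r.spec.packages]
        a = _layer0_output(reg_py, reqs_py)
        b = _layer0_output(reg_r, reqs_r, language="r-stack")
        return a, b

    def test_merge_installs_both_sets_and_sums_volumes(self):
        a, b = self._two_stacks()
        merged = merge_layer0_outputs(a, b)
        assert merged.folder_name == "1_mergeDocker"
        names = {p.name for p in merged.manifest.packages}
        assert names == {p.name for p in a.manifest.packages} | {
            p.name for p in b.manifest.packages
        }
        n_vols = sum(len(g.chunkset.volumes) for g in merged.chunk_groups)
        assert n_vols == len(a.chunkset.volumes) + len(b.chunkset.volumes)
        assert scan_offline_closure(merged.dockerfile_text) == []

    def test_merge_with_empty_stack_is_neutral(self, diamond_registry, request_a):
        a = _layer0_output(diamond_registry, request_a)
        empty = _layer0_output(diamond_registry, [], language="r-stack")
        merged = merge_layer0_outputs(a, empty)
        assert {(p.name, p.version) for p in merged.manifest.packages} == {
            (p.name, p.version) for p in a.manifest.packages
        }

    def test_merge_commutes_on_install_multisets(self):
        a, b = self._two_stacks()
        ab = merge_layer0_outputs(a, b)
        ba = merge_layer0_outputs(b, a)
        key = lambda m: sorted((p.name, p.ecosystem, p.version) for p in m.manifest.packages)
        assert key(ab) == key(ba)

    def test_differing_base_digests_refused(self, diamond_registry, request_a):
        a = _layer0_output(diamond_registry, request_a)
        backend = MockSandboxBackend(diamond_registry)
        manifest, files = capture_install([], backend, diamond_registry,
                                          base_image_ref="ubuntu@sha256:" + "f" * 64)
        b = build_layer_output(LayerConfig(0, options={"language": "r-stack"}),
                               manifest, files, image_name="credimage")
        with pytest.raises(ForgeError, match="base image"):
            merge_layer0_outputs(a, b)

    def test_merge_requires_layer0_inputs(self, out0):
        not0 = build_layer_output(LayerConfig(4), out0.manifest, {}, image_name="credimage")
        with pytest.raises(ForgeError):
            merge_layer0_outputs(out0, not0)


def _plan_01(host_path, mode="permissive"):
    return BuildPlan(
        layers=[LayerConfig(0, options={"language": "python-stack"}), LayerConfig(1)],
        mode=mode,
        image_name="credimage",
        host_path=str(host_path),
    )


REQUIRED_FILES = {"Dockerfile", "script.sh", "script.cmd", "manifest.json",
                  "install_offline.sh", "chunkset.json"}


class TestAssemble:
    def test_plan_01_layout(self, tmp_path, diamond_registry, request_a):
        plan = _plan_01(tmp_path / "out")
        backend = MockSandboxBackend(diamond_registry)
        outputs = build_plan_outputs(plan, {0: request_a, 1: []}, diamond_registry, backend)
        layout = assemble_output_folder(plan, outputs)
        assert set(layout) == {"0_PythonPackages", "1_mergeDocker"}
        for folder, files in layout.items():
            assert REQUIRED_FILES <= set(files)
            assert os.path.isfile(tmp_path / "out" / folder / "Dockerfile")
        index = (tmp_path / "out" / "layers.txt").read_text().split()
        assert index == ["0_PythonPackages", "1_mergeDocker"]

    def test_layer2_folder_name_contains_gui(self, tmp_path, diamond_registry, request_a):
        plan = BuildPlan(
            layers=[
                LayerConfig(0, options={"language": "python-stack"}),
                LayerConfig(1),
                LayerConfig(2, options={"gui": "jupyterlab"}),
            ],
            image_name="credimage",
            host_path=str(tmp_path / "out"),
        )
        backend = MockSandboxBackend(diamond_registry)
        outputs = build_plan_outputs(plan, {0: request_a}, diamond_registry, backend)
        layout = assemble_output_folder(plan, outputs)
        assert any("jupyterlab" in folder for folder in layout)

    def test_empty_plan_rejected(self, tmp_path):
        with pytest.raises(PlanValidationError):
            assemble_output_folder(BuildPlan(layers=[], host_path=str(tmp_path)), [])

    def test_existing_nonempty_folder_needs_overwrite(self, tmp_path, diamond_registry, request_a):
        plan = _plan_01(tmp_path / "out")
        backend = MockSandboxBackend(diamond_registry)
        outputs = build_plan_outputs(plan, {0: request_a, 1: []}, diamond_registry, backend)
        assemble_output_folder(plan, outputs)
        with pytest.raises(ForgeError, match="non-empty"):
            assemble_output_folder(plan, outputs)
        assemble_output_folder(plan, outputs, overwrite=True)  # flag allows rewrite

    def test_volume_files_match_dockerfile_references(self, tmp_path, diamond_registry, request_a):
        """No orphans: every volume in the folder is referenced and vice versa."""
        plan = _plan_01(tmp_path / "out")
        backend = MockSandboxBackend(diamond_registry)
        outputs = build_plan_outputs(plan, {0: request_a, 1: []}, diamond_registry, backend)
        assemble_output_folder(plan, outputs)
        for output in outputs:
            folder = tmp_path / "out" / output.folder_name
            on_disk = {f.name for f in folder.iterdir() if ".part" in f.name}
            referenced = {
                v.filename for g in output.chunk_groups for v in g.chunkset.volumes
            }
            assert on_disk == referenced
            for fname in referenced:
                assert fname in output.dockerfile_text


class TestEndToEndDeterminism:
    def test_two_runs_byte_identical_excluding_logs(self, tmp_path, diamond_registry, request_a):
        plan_args = dict(mode="permissive", image_name="credimage")

        def run(root):
            plan = BuildPlan(
                layers=[LayerConfig(0, options={"language": "python-stack"}), LayerConfig(1)],
                host_path=str(root), **plan_args,
            )
            backend = MockSandboxBackend(diamond_registry)
            outputs = build_plan_outputs(plan, {0: request_a, 1: []}, diamond_registry, backend)
            assemble_output_folder(plan, outputs)

        run(tmp_path / "r1")
        run(tmp_path / "r2")
        files1 = sorted(
            p.relative_to(tmp_path / "r1")
            for p in (tmp_path / "r1").rglob("*") if p.is_file()
        )
        files2 = sorted(
            p.relative_to(tmp_path / "r2")
            for p in (tmp_path / "r2").rglob("*") if p.is_file()
        )
        assert files1 == files2
        for rel in files1:
            if rel.name == "forge.log":
                continue  # timestamps excluded by design
            assert (tmp_path / "r1" / rel).read_bytes() == (tmp_path / "r2" / rel).read_bytes(), rel
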