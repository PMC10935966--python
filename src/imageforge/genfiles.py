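"""Phase 2 — emit self-contained, offline-buildable output folders.

For each planned layer this module generates a folder holding everything a
later (possibly air-gapped) build needs: the Dockerfile, the chunked
archive volumes with their manifest, the capture manifest, the offline
install script, and a POSIX ``script.sh`` / Windows ``script.cmd`` pair
that builds and runs the image.

Two rules are enforced mechanically rather than by convention:

* **offline closure** — the only remote reference a generated Dockerfile
  may contain is its base-image line; :func:`scan_offline_closure` is the
  checkable form of that rule and every emitted Dockerfile must pass it;
* **layer lineage** — layers >= 1 build ``FROM`` the previous layer's
  image tag instead of repeating its instructions.

Runtime conventions baked into the scripts: the run command pins
``--platform linux/amd64``; a host directory is mounted at
``/sharedFolder``; layers 0–1 drop into an interactive shell while layers
2–3 publish the single GUI port 8888 and stay detached.
"""

from __future__ import annotations

import datetime
import os
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .capture import CaptureManifest, generate_offline_install_script
from .chunks import DEFAULT_VOLUME_LIMIT, ChunkSet, chunk_files
from .core import (
    GUI_CHOICES,
    VM_CHOICES,
    BuildPlan,
    LayerConfig,
    layer_folder_name,
    validate_image_name,
    validate_layer_plan,
)
from .errors import DockerfileParseError, ForgeError, PlanValidationError

#: The one container port GUIs listen on; published to the same host port.
GUI_PORT = 8888
SHARED_MOUNT = "/sharedFolder"
DEFAULT_IMAGE_NAME = "forgedimage"

_GUI_COMMANDS = {
    "jupyterlab": '["jupyter", "lab", "--ip=0.0.0.0", "--port=8888", "--no-browser", "--allow-root"]',
    "jupyternotebook": '["jupyter", "notebook", "--ip=0.0.0.0", "--port=8888", "--no-browser", "--allow-root"]',
    "rstudio": '["rserver", "--www-address=0.0.0.0", "--www-port=8888", "--server-daemonize=0"]',
    "visualstudio": '["code-server", "--bind-addr", "0.0.0.0:8888", "--auth", "none"]',
}


@dataclass(frozen=True)
class ChunkGroup:
    """One chunked archive stream of a layer (merged layers carry two)."""

    prefix: str
    chunkset: ChunkSet
    volumes: dict[str, bytes]


@dataclass
class LayerOutput:
    """Everything written into one layer's output folder."""

    layer: LayerConfig
    folder_name: str
    dockerfile_text: str
    run_script_posix: str
    run_script_windows: str
    manifest: CaptureManifest
    chunk_groups: list[ChunkGroup]
    image_name: str
    shared_host_path: str
    log_lines: list[str] = field(default_factory=list)

    @property
    def chunkset(self) -> ChunkSet:
        return self.chunk_groups[0].chunkset

    def volume_files(self) -> dict[str, bytes]:
        out: dict[str, bytes] = {}
        for group in self.chunk_groups:
            out.update(group.volumes)
        return out


def image_tag(image_name: str, layer_number: int) -> str:
    return f"{image_name}:layer{layer_number}"


# ---------------------------------------------------------------------------
# Dockerfile generation

def generate_dockerfile(
    layer: LayerConfig,
    manifest: CaptureManifest,
    chunk_groups: Sequence[ChunkGroup],
    parent_image: Optional[str] = None,
) -> str:
    """Emit one layer's Dockerfile.

    Layer 0 builds ``FROM`` the digest-pinned base image; layers >= 1 build
    from ``parent_image`` (the previous layer's tag).  All volumes are
    copied into the build context target, reassembled, and installed by the
    offline script; nothing else is fetched.
    """
    if layer.number == 2:
        gui = layer.options.get("gui")
        if gui is None or gui not in GUI_CHOICES:
            raise ForgeError(
                f"layer 2 requires exactly one gui option of {GUI_CHOICES}, got {gui!r}"
            )
    for group in chunk_groups:
        total = sum(v.byte_size for v in group.chunkset.volumes)
        if total != group.chunkset.total_stream_bytes:
            raise ForgeError("chunkset volume sizes disagree with total_stream_bytes")
        for vol in group.chunkset.volumes:
            if vol.filename not in group.volumes:
                raise ForgeError(f"volume content missing for {vol.filename}")

    base = parent_image if parent_image is not None else manifest.base_image_ref
    lines = [
        f"FROM {base}",
        "LABEL org.imageforge.layer=" + f'"{layer.number}_{layer.slug}"',
        "WORKDIR /build",
    ]
    for group in chunk_groups:
        cs = group.chunkset
        if not cs.volumes:
            continue
        for vol in cs.volumes:
            lines.append(f"COPY {vol.filename} /build/chunks/{vol.filename}")
        cat_list = " ".join(f"/build/chunks/{v.filename}" for v in cs.volumes)
        stream = f"/build/{group.prefix or 'main'}_stream.tar.gz"
        lines.append(
            f"RUN cat {cat_list} > {stream} && "
            f"mkdir -p /build && tar -xzf {stream} -C /build && "
            f"rm -rf {stream} /build/chunks"
        )
    lines.append("COPY install_offline.sh /build/install_offline.sh")
    if manifest.packages or manifest.env_specs:
        lines.append("RUN cd /build && sh ./install_offline.sh")
    lines.append(f"RUN mkdir -p {SHARED_MOUNT}")

    if layer.number == 2:
        gui = layer.options["gui"]
        lines.append(f"EXPOSE {GUI_PORT}")
        lines.append(f"CMD {_GUI_COMMANDS[gui]}")
    elif layer.number == 3:
        vm = layer.options.get("vm")
        if vm not in VM_CHOICES:
            raise ForgeError(f"layer 3 requires vm option of {VM_CHOICES}, got {vm!r}")
        if vm == "docker":
            lines.append("VOLUME /var/lib/docker")
            lines.append("ENV FORGE_NESTED_RUNTIME=docker")
        else:
            lines.append("ENV FORGE_NESTED_RUNTIME=singularity")
            lines.append("ENV SINGULARITY_TMPDIR=/tmp/singularity")
        lines.append(f"EXPOSE {GUI_PORT}")
        lines.append('CMD ["bash"]')
    else:
        lines.append('CMD ["bash"]')

    text = "\n".join(lines) + "\n"
    violations = scan_offline_closure(text)
    if violations:
        raise ForgeError(f"generated Dockerfile is not offline-closed: {violations}")
    return text


# ---------------------------------------------------------------------------
# run scripts

def generate_run_scripts(
    layer: LayerConfig,
    image_name: str,
    shared_host_path: str,
    host_port: int = GUI_PORT,
) -> tuple[str, str]:
    """Build+run scripts in POSIX sh and Windows batch dialects.

    Both reference the same image tag and mount target.  Layers 0–1 attach
    an interactive shell; layers >= 2 publish the GUI port and detach.
    """
    verdict = validate_image_name(image_name)
    if not verdict:
        raise ForgeError(f"invalid image name {image_name!r}: {', '.join(verdict.violations)}")
    if not shared_host_path:
        raise ForgeError("shared_host_path must be non-empty")
    tag = image_tag(image_name, layer.number)
    interactive = layer.number < 2

    posix = [
        "#!/bin/sh",
        "set -e",
        f'IMAGE="{tag}"',
        f'SHARED_DIR="${{SHARED_DIR:-{shared_host_path}}}"',
        f'MOUNT_POINT="${{MOUNT_POINT:-{SHARED_MOUNT}}}"',
        'docker build --platform linux/amd64 -t "$IMAGE" .',
    ]
    win = [
        "@echo off",
        f"set IMAGE={tag}",
        f"set SHARED_DIR={shared_host_path}",
        f"set MOUNT_POINT={SHARED_MOUNT}",
        "docker build --platform linux/amd64 -t %IMAGE% .",
    ]
    if interactive:
        posix.append(
            'docker run --platform linux/amd64 -v "$SHARED_DIR":"$MOUNT_POINT" -it "$IMAGE" bash'
        )
        win.append(
            'docker run --platform linux/amd64 -v "%SHARED_DIR%":"%MOUNT_POINT%" -it %IMAGE% bash'
        )
    else:
        posix.append(f'HOST_PORT="${{HOST_PORT:-{host_port}}}"')
        posix.append(
            'docker run --platform linux/amd64 -v "$SHARED_DIR":"$MOUNT_POINT" '
            f'-p "$HOST_PORT":{GUI_PORT} -d "$IMAGE"'
        )
        posix.append(f'echo "open http://localhost:$HOST_PORT"')
        win.append(f"set HOST_PORT={host_port}")
        win.append(
            'docker run --platform linux/amd64 -v "%SHARED_DIR%":"%MOUNT_POINT%" '
            f"-p %HOST_PORT%:{GUI_PORT} -d %IMAGE%"
        )
        win.append("echo open http://localhost:%HOST_PORT%")
    return "\n".join(posix) + "\n", "\r\n".join(win) + "\r\n"


# ---------------------------------------------------------------------------
# offline-closure scanner

@dataclass(frozen=True)
class Violation:
    line: int
    instruction: str
    pattern: str

    def __str__(self) -> str:
        return f"line {self.line}: {self.pattern} in {self.instruction!r}"


_INSTRUCTIONS = {
    "FROM", "RUN", "CMD", "LABEL", "EXPOSE", "ENV", "ADD", "COPY", "ENTRYPOINT",
    "VOLUME", "USER", "WORKDIR", "ARG", "ONBUILD", "STOPSIGNAL", "HEALTHCHECK",
    "SHELL", "MAINTAINER",
}

#: (human-readable name, compiled regex). A hit in any instruction other
#: than the base-image FROM line is a violation.
_DENY_PATTERNS: list[tuple[str, re.Pattern]] = [
    ("url scheme", re.compile(r"\b(?:https?|ftp|git|ssh)://", re.IGNORECASE)),
    ("git clone", re.compile(r"\bgit\s+clone\b")),
    ("curl", re.compile(r"\bcurl\b")),
    ("wget", re.compile(r"\bwget\b")),
    ("apt network verb", re.compile(r"\bapt(?:-get)?\s+(?:update|install|upgrade|dist-upgrade)\b")),
    ("pip network install", re.compile(r"\bpip3?\s+(?:install|download)\b(?![^\n]*--no-index)")),
    ("conda network verb", re.compile(r"\b(?:conda|mamba|micromamba)\s+(?:install|create)\b(?![^\n]*--offline)")),
    ("R network install", re.compile(r"install\.packages\(|BiocManager::install|devtools::install_github")),
    ("npm install", re.compile(r"\bnpm\s+(?:install|ci)\b(?![^\n]*--offline)")),
    ("go get", re.compile(r"\bgo\s+get\b")),
    ("docker pull", re.compile(r"\bdocker\s+pull\b")),
]


def _logical_lines(text: str) -> list[tuple[int, str]]:
    """Join backslash-continued lines; skip blanks and comments.

    Returns (1-based starting line number, logical line) pairs.
    """
    out: list[tuple[int, str]] = []
    physical = text.replace("\r\n", "\n").split("\n")
    i = 0
    while i < len(physical):
        raw = physical[i]
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            i += 1
            continue
        start = i + 1
        logical = stripped
        while logical.endswith("\\") and i + 1 < len(physical):
            i += 1
            logical = logical[:-1] + " " + physical[i].strip()
        out.append((start, logical))
        i += 1
    return out


def scan_offline_closure(dockerfile_text: str) -> list[Violation]:
    """Report every instruction that would reach the network.

    The first ``FROM`` line is the single permitted remote reference (the
    pinned base image); everything else must resolve from the build
    context.  Raises :class:`DockerfileParseError` when the text is not a
    sequence of Dockerfile instructions.
    """
    violations: list[Violation] = []
    seen_from = False
    for lineno, logical in _logical_lines(dockerfile_text):
        keyword = logical.split(None, 1)[0].upper()
        if keyword not in _INSTRUCTIONS:
            raise DockerfileParseError(
                f"line {lineno}: not a Dockerfile instruction: {logical!r}"
            )
        if keyword == "FROM" and not seen_from:
            seen_from = True
            continue  # the one permitted remote reference
        for name, pattern in _DENY_PATTERNS:
            if pattern.search(logical):
                violations.append(Violation(line=lineno, instruction=logical, pattern=name))
    if not seen_from:
        raise DockerfileParseError("no FROM instruction found")
    return violations


# ---------------------------------------------------------------------------
# layer output construction, merge, assembly

def build_layer_output(
    layer: LayerConfig,
    manifest: CaptureManifest,
    artifact_files: dict[str, bytes],
    image_name: str = DEFAULT_IMAGE_NAME,
    shared_host_path: str = "./sharedFolder",
    volume_limit: int = DEFAULT_VOLUME_LIMIT,
    parent_image: Optional[str] = None,
) -> LayerOutput:
    """Chunk a layer's artifacts and emit its complete folder content."""
    files = [(f"artifacts/{fname}", content) for fname, content in sorted(artifact_files.items())]
    chunkset, volumes = chunk_files(files, limit=volume_limit, stem="layerdata")
    group = ChunkGroup(prefix="", chunkset=chunkset, volumes=volumes)
    dockerfile = generate_dockerfile(layer, manifest, [group], parent_image=parent_image)
    posix, win = generate_run_scripts(layer, image_name, shared_host_path)
    return LayerOutput(
        layer=layer,
        folder_name=layer_folder_name(layer),
        dockerfile_text=dockerfile,
        run_script_posix=posix,
        run_script_windows=win,
        manifest=manifest,
        chunk_groups=[group],
        image_name=image_name,
        shared_host_path=shared_host_path,
        log_lines=[f"generated layer {layer.number} ({layer.slug})"],
    )


def _prefixed_groups(output: LayerOutput, prefix: str) -> list[ChunkGroup]:
    groups = []
    for group in output.chunk_groups:
        sub = f"{prefix}{group.prefix}" if group.prefix else prefix.rstrip("_")
        renamed_vols = {}
        new_infos = []
        for vol in group.chunkset.volumes:
            new_name = f"{prefix}{vol.filename}"
            renamed_vols[new_name] = group.volumes[vol.filename]
            new_infos.append(replace(vol, filename=new_name))
        cs = ChunkSet(
            volumes=new_infos,
            total_stream_bytes=group.chunkset.total_stream_bytes,
            volume_limit_bytes=group.chunkset.volume_limit_bytes,
            stream_checksum=group.chunkset.stream_checksum,
            entry_index=list(group.chunkset.entry_index),
            stem=f"{prefix}{group.chunkset.stem}",
        )
        groups.append(ChunkGroup(prefix=sub, chunkset=cs, volumes=renamed_vols))
    return groups


def merge_layer0_outputs(a: LayerOutput, b: LayerOutput) -> LayerOutput:
    """Merge two layer-0 stacks (Python + R) into the layer-1 output.

    Both inputs must share the base image digest (no silent rebase).  The
    merged manifest installs a's stack then b's; chunk volumes keep their
    own streams, renamed with per-source prefixes so filenames cannot
    collide.  Packages identical in (name, ecosystem, version) are
    installed once.
    """
    if a.layer.number != 0 or b.layer.number != 0:
        raise ForgeError("merge_layer0_outputs requires two layer-0 outputs")
    if a.manifest.base_image_ref != b.manifest.base_image_ref:
        raise ForgeError(
            "cannot merge outputs with differing base image digests: "
            f"{a.manifest.base_image_ref} != {b.manifest.base_image_ref}"
        )

    merged_pkgs = []
    seen: set[tuple[str, str, str]] = set()
    for pkg in sorted(a.manifest.packages, key=lambda p: p.install_index) + sorted(
        b.manifest.packages, key=lambda p: p.install_index
    ):
        key = (pkg.name, pkg.ecosystem, pkg.version)
        if key in seen:
            continue
        seen.add(key)
        merged_pkgs.append(replace(pkg, install_index=len(merged_pkgs)))

    env_specs = list(a.manifest.env_specs)
    for env in b.manifest.env_specs:
        if env not in env_specs:
            env_specs.append(env)

    merged_manifest = CaptureManifest(
        packages=merged_pkgs,
        env_specs=env_specs,
        base_image_ref=a.manifest.base_image_ref,
        created_at=a.manifest.created_at,
    )
    merged_manifest.install_script = generate_offline_install_script(merged_manifest)

    layer1 = LayerConfig(number=1, slug="mergeDocker")
    groups = _prefixed_groups(a, "s0_") + _prefixed_groups(b, "s1_")
    dockerfile = generate_dockerfile(layer1, merged_manifest, groups, parent_image=None)
    posix, win = generate_run_scripts(layer1, a.image_name, a.shared_host_path)
    return LayerOutput(
        layer=layer1,
        folder_name="1_mergeDocker",
        dockerfile_text=dockerfile,
        run_script_posix=posix,
        run_script_windows=win,
        manifest=merged_manifest,
        chunk_groups=groups,
        image_name=a.image_name,
        shared_host_path=a.shared_host_path,
        log_lines=[f"merged {a.folder_name} + {b.folder_name}"],
    )


def assemble_output_folder(
    plan: BuildPlan,
    outputs: Sequence[LayerOutput],
    host_path: Optional[str] = None,
    overwrite: bool = False,
) -> dict[str, list[str]]:
    """Write one folder per layer under the host path; return the layout.

    Each folder receives the Dockerfile, all chunk volumes, the chunkset
    manifest, the capture manifest, the offline install script, both run
    scripts, and a build log.  ``layers.txt`` at the top level indexes the
    folders in plan order.  A pre-existing non-empty layer folder is an
    error unless ``overwrite`` is set.
    """
    violations = validate_layer_plan(plan)
    if violations:
        raise PlanValidationError(violations)
    if len(outputs) != len(plan.layers):
        raise ForgeError(
            f"plan has {len(plan.layers)} layers but {len(outputs)} outputs were supplied"
        )
    root = host_path or plan.host_path
    if not root:
        raise ForgeError("no host path: set plan.host_path or pass host_path")
    os.makedirs(root, exist_ok=True)
    if not os.access(root, os.W_OK):
        raise ForgeError(f"host path not writable: {root}")

    layout: dict[str, list[str]] = {}
    for output in outputs:
        folder = os.path.join(root, output.folder_name)
        if os.path.isdir(folder) and os.listdir(folder) and not overwrite:
            raise ForgeError(f"refusing to write into non-empty folder: {folder}")
        os.makedirs(folder, exist_ok=True)
        written: list[str] = []

        def _write(name: str, data, mode: str = "w", newline="\n"):
            path = os.path.join(folder, name)
            if mode == "wb":
                with open(path, "wb") as fh:
                    fh.write(data)
            else:
                with open(path, "w", newline=newline) as fh:
                    fh.write(data)
            written.append(name)

        _write("Dockerfile", output.dockerfile_text)
        _write("script.sh", output.run_script_posix)
        os.chmod(os.path.join(folder, "script.sh"), 0o755)
        _write("script.cmd", output.run_script_windows, newline="")
        _write("manifest.json", output.manifest.to_json(include_timestamp=False))
        _write("install_offline.sh", output.manifest.install_script)
        chunks_doc = {
            "groups": [
                {"prefix": g.prefix, "chunkset": g.chunkset.to_dict()}
                for g in output.chunk_groups
            ]
        }
        import json as _json

        _write("chunkset.json", _json.dumps(chunks_doc, sort_keys=True, indent=2) + "\n")
        for fname, content in sorted(output.volume_files().items()):
            _write(fname, content, mode="wb")
        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        log_text = "\n".join([f"[{stamp}] assemble {output.folder_name}"] + output.log_lines)
        _write("forge.log", log_text + "\n")
        layout[output.folder_name] = sorted(written)

    index = "\n".join(o.folder_name for o in outputs) + "\n"
    with open(os.path.join(root, "layers.txt"), "w", newline="\n") as fh:
        fh.write(index)
    return layout


# ---------------------------------------------------------------------------
# whole-plan pipeline

def build_plan_outputs(
    plan: BuildPlan,
    requests_by_layer: dict[int, list],
    registry,
    backend,
    volume_limit: int = DEFAULT_VOLUME_LIMIT,
    shared_host_path: str = "./sharedFolder",
) -> list[LayerOutput]:
    """Capture + emit every layer of a validated plan, chained by lineage.

    ``requests_by_layer`` maps layer number -> package requests captured for
    that layer.  When the plan contains layer 1, its requests are captured
    as a second layer-0 stack and merged with layer 0's output.  Layers
    >= 2 build FROM the previous emitted layer's image tag.
    """
    from .capture import capture_install

    violations = validate_layer_plan(plan)
    if violations:
        raise PlanValidationError(violations)
    image_name = plan.image_name or DEFAULT_IMAGE_NAME

    outputs: list[LayerOutput] = []
    prev_number: Optional[int] = None
    for layer in plan.layers:
        reqs = requests_by_layer.get(layer.number, [])
        if layer.number == 1 and outputs and outputs[-1].layer.number == 0:
            other0 = LayerConfig(number=0, options={"language": "r-stack"})
            manifest_b, files_b = capture_install(reqs, backend, registry)
            out_b = build_layer_output(
                other0, manifest_b, files_b,
                image_name=image_name, shared_host_path=shared_host_path,
                volume_limit=volume_limit,
            )
            output = merge_layer0_outputs(outputs[-1], out_b)
        else:
            manifest, files = capture_install(reqs, backend, registry)
            parent = image_tag(image_name, prev_number) if prev_number is not None else None
            output = build_layer_output(
                layer, manifest, files,
                image_name=image_name, shared_host_path=shared_host_path,
                volume_limit=volume_limit, parent_image=parent,
            )
        outputs.append(output)
        prev_number = layer.number
    return outputs
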