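"""Phase 1 — capture: resolve, download, record.

Every requested package and its full dependency closure is resolved against
a registry catalog, fetched inside a disposable sandbox (a "dummy"
container in the real world; a mock in tests), and recorded in a
:class:`CaptureManifest`: exact versions, artifact files with SHA-256
checksums, a dependency-respecting install order, and the generated
offline install script.  The sandbox is always destroyed afterwards,
whether capture succeeded or failed.

The registry is an abstract catalog (:class:`Registry`); the capture logic
never talks to a network itself, so everything above the driver is testable
offline.
"""

from __future__ import annotations

import hashlib
import heapq
import json
import os
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Optional, Protocol, Sequence

from .core import PackageRequest
from .errors import BackendError, DependencyCycleError, ForgeError, ResolutionError

#: Digest-pinned base image reference used when the caller does not supply
#: one.  The digest is a fixed constant so generated folders are
#: reproducible; a live deployment would record the registry digest of the
#: actual base image pulled at capture time.
DEFAULT_BASE_IMAGE = "ubuntu@sha256:" + hashlib.sha256(b"ubuntu:22.04").hexdigest()

#: Container path under which conda/bioconda environments are rooted, so
#: ``source /snowflakes/<name>/bin/activate`` always works.
SNOWFLAKES_ROOT = "/snowflakes"


class Registry(Protocol):
    """Catalog interface every ecosystem driver (and the mock) implements."""

    def versions(self, name: str, ecosystem: str) -> list[str]:
        """Available versions, unsorted; empty/KeyError if unknown."""
        ...

    def dependencies(self, name: str, ecosystem: str, version: str) -> list[tuple[str, str]]:
        """Direct dependencies of one version as (name, ecosystem) pairs."""
        ...

    def artifact(self, name: str, ecosystem: str, version: str) -> tuple[str, bytes]:
        """(filename, content) of the downloadable artifact."""
        ...


class SandboxBackend(Protocol):
    """The disposable capture environment.

    ``destroy`` must be safe to call exactly once per session and is always
    called, on success or failure.
    """

    def start(self, base_image_ref: str) -> object: ...

    def run(self, session: object, command: str) -> tuple[int, str]: ...

    def collect_files(self, session: object, path: str) -> dict[str, bytes]: ...

    def destroy(self, session: object) -> None: ...


@dataclass(frozen=True)
class ResolvedPackage:
    """One member of the resolved closure.

    ``artifact_file``/``byte_size``/``checksum`` are empty until the
    artifact has actually been collected by :func:`capture_install`.
    """

    name: str
    ecosystem: str
    version: str
    install_index: int
    depends_on: tuple[tuple[str, str], ...] = ()
    artifact_file: str = ""
    byte_size: int = 0
    checksum: str = ""


@dataclass(frozen=True)
class EnvSpec:
    """A conda/bioconda environment rooted under /snowflakes."""

    env_name: str
    kind: str  # "conda" | "bioconda"

    @property
    def target_path(self) -> str:
        return f"{SNOWFLAKES_ROOT}/{self.env_name}"


@dataclass
class CaptureManifest:
    """The machine-readable phase-1 record.

    ``created_at`` is informational only and excluded from the canonical
    serialization, which is byte-deterministic for a fixed input.
    """

    packages: list[ResolvedPackage]
    env_specs: list[EnvSpec] = field(default_factory=list)
    install_script: str = ""
    base_image_ref: str = DEFAULT_BASE_IMAGE
    created_at: Optional[str] = None

    def to_dict(self, include_timestamp: bool = False) -> dict:
        d = {
            "base_image_ref": self.base_image_ref,
            "packages": [
                {
                    "name": p.name,
                    "ecosystem": p.ecosystem,
                    "version": p.version,
                    "install_index": p.install_index,
                    "depends_on": [list(dep) for dep in p.depends_on],
                    "artifact_file": p.artifact_file,
                    "byte_size": p.byte_size,
                    "checksum": p.checksum,
                }
                for p in sorted(self.packages, key=lambda p: p.install_index)
            ],
            "env_specs": [
                {"env_name": e.env_name, "kind": e.kind, "target_path": e.target_path}
                for e in self.env_specs
            ],
            "install_script": self.install_script,
        }
        if include_timestamp and self.created_at is not None:
            d["created_at"] = self.created_at
        return d

    def to_json(self, include_timestamp: bool = False) -> str:
        """Canonical JSON: sorted keys, LF endings, trailing newline."""
        return json.dumps(self.to_dict(include_timestamp), sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_dict(cls, d: dict) -> "CaptureManifest":
        return cls(
            packages=[
                ResolvedPackage(
                    name=p["name"],
                    ecosystem=p["ecosystem"],
                    version=p["version"],
                    install_index=p["install_index"],
                    depends_on=tuple((n, e) for n, e in p["depends_on"]),
                    artifact_file=p["artifact_file"],
                    byte_size=p["byte_size"],
                    checksum=p["checksum"],
                )
                for p in d["packages"]
            ],
            env_specs=[EnvSpec(e["env_name"], e["kind"]) for e in d.get("env_specs", [])],
            install_script=d.get("install_script", ""),
            base_image_ref=d["base_image_ref"],
            created_at=d.get("created_at"),
        )

    @classmethod
    def from_json(cls, text: str) -> "CaptureManifest":
        return cls.from_dict(json.loads(text))


def _version_key(version: str):
    # natural-order key: numeric runs compare as integers
    parts: list[tuple[int, object]] = []
    num = ""
    for c in version:
        if c.isdigit():
            num += c
        else:
            if num:
                parts.append((1, int(num)))
                num = ""
            parts.append((0, c))
    if num:
        parts.append((1, int(num)))
    return parts


def _select_version(
    name: str, ecosystem: str, registry: Registry, pin: Optional[str]
) -> str:
    try:
        available = list(registry.versions(name, ecosystem))
    except KeyError:
        available = []
    if not available:
        raise ResolutionError(f"unknown package {ecosystem}:{name}")
    if pin is not None:
        if pin not in available:
            raise ResolutionError(
                f"version {pin!r} of {ecosystem}:{name} unavailable (have {sorted(available)})"
            )
        return pin
    return max(available, key=_version_key)


def resolve_dependencies(
    requests: Sequence[PackageRequest], registry: Registry
) -> list[ResolvedPackage]:
    """Resolve the dependency closure into a deterministic install order.

    The order is a valid topological order of the recorded dependency
    graph; among admissible orders, ties break by lexicographic
    ``(ecosystem, name)``, i.e. the lexicographically smallest topological
    order.  Version selection is the exact pin when requested, otherwise
    the highest available (natural version order).  Each package appears
    once.  Unknown packages, unavailable pins and dependency cycles raise.
    """
    pins: dict[tuple[str, str], str] = {}
    for req in requests:
        key = (req.name, req.ecosystem)
        if req.version is not None:
            if pins.get(key, req.version) != req.version:
                raise ResolutionError(f"conflicting pins for {req.ecosystem}:{req.name}")
            pins[key] = req.version

    # Build the closure: key -> (version, deps)
    resolved: dict[tuple[str, str], tuple[str, tuple[tuple[str, str], ...]]] = {}
    stack = [(req.name, req.ecosystem) for req in requests]
    while stack:
        name, eco = stack.pop()
        key = (name, eco)
        if key in resolved:
            continue
        version = _select_version(name, eco, registry, pins.get(key))
        deps = tuple(
            (dn, de) for dn, de in registry.dependencies(name, eco, version)
        )
        resolved[key] = (version, deps)
        stack.extend(deps)

    # Kahn's algorithm with a min-heap on (ecosystem, name): yields the
    # lexicographically smallest topological order.
    indeg = {key: 0 for key in resolved}
    dependents: dict[tuple[str, str], list[tuple[str, str]]] = {k: [] for k in resolved}
    for key, (_, deps) in resolved.items():
        for dep in deps:
            indeg[key] += 1
            dependents[dep].append(key)
    heap = [(eco, name) for (name, eco), d in indeg.items() if d == 0]
    heapq.heapify(heap)
    order: list[ResolvedPackage] = []
    while heap:
        eco, name = heapq.heappop(heap)
        key = (name, eco)
        version, deps = resolved[key]
        order.append(
            ResolvedPackage(
                name=name,
                ecosystem=eco,
                version=version,
                install_index=len(order),
                depends_on=deps,
            )
        )
        for dep_key in dependents[key]:
            indeg[dep_key] -= 1
            if indeg[dep_key] == 0:
                heapq.heappush(heap, (dep_key[1], dep_key[0]))
    if len(order) != len(resolved):
        remaining = [k for k in resolved if indeg[k] > 0]
        cycle = _find_cycle(remaining, resolved)
        raise DependencyCycleError(cycle)
    return order


def _find_cycle(nodes, resolved) -> list[tuple[str, str]]:
    node_set = set(nodes)
    start = min(nodes, key=lambda k: (k[1], k[0]))
    path, seen = [start], {start}
    cur = start
    while True:
        deps = [d for d in resolved[cur][1] if d in node_set]
        nxt = min(deps, key=lambda k: (k[1], k[0]))
        if nxt in seen:
            return path[path.index(nxt):]
        path.append(nxt)
        seen.add(nxt)
        cur = nxt


# ---------------------------------------------------------------------------
# offline install script generation

_INSTALL_TEMPLATES = {
    "pypi-like": "python -m pip install --no-index --no-deps ./artifacts/{file}",
    "cran-like": "R CMD INSTALL ./artifacts/{file}",
    "bioconductor-like": "R CMD INSTALL ./artifacts/{file}",
    "apt": "dpkg -i ./artifacts/{file}",
    "source-host": (
        "mkdir -p /usr/local/src/{name} && tar -xzf ./artifacts/{file} -C /usr/local/src/{name}"
    ),
    "conda": "conda install --offline --yes --prefix {env_path} ./artifacts/{file}",
    "bioconda": "conda install --offline --yes --prefix {env_path} ./artifacts/{file}",
}

_MARKER_DIR = "/var/lib/forge/installed"


def generate_offline_install_script(
    manifest: CaptureManifest,
    available_files: Optional[Iterable[str]] = None,
) -> str:
    """Emit the POSIX install script that phase 2 bakes into the Dockerfile.

    Installs strictly in ``install_index`` order from files relative to the
    build-context unpack directory; contains no remote locator.  Re-running
    the script is a no-op thanks to per-package marker files.  If
    ``available_files`` is given, a manifest entry referencing a file not in
    it raises before any text is produced.
    """
    pkgs = sorted(manifest.packages, key=lambda p: p.install_index)
    for p in pkgs:
        if not p.artifact_file:
            raise ForgeError(f"package {p.ecosystem}:{p.name} has no recorded artifact file")
    if available_files is not None:
        have = set(available_files)
        for p in pkgs:
            if p.artifact_file not in have:
                raise ForgeError(f"artifact file missing: {p.artifact_file}")

    env_by_kind = {e.kind: e for e in manifest.env_specs}
    lines = [
        "#!/bin/sh",
        "# generated offline install script -- installs from ./artifacts only",
        "set -e",
        f"mkdir -p {_MARKER_DIR}",
    ]
    for env in manifest.env_specs:
        lines += [
            f'if [ ! -d "{env.target_path}/bin" ]; then',
            f"  mkdir -p {env.target_path}",
            f"  conda create --offline --yes --prefix {env.target_path}",
            "fi",
        ]
    for p in pkgs:
        marker = f"{_MARKER_DIR}/{p.ecosystem}__{p.name}__{p.version}"
        env = env_by_kind.get(p.ecosystem)
        env_path = env.target_path if env else f"{SNOWFLAKES_ROOT}/{p.name}"
        cmd = _INSTALL_TEMPLATES[p.ecosystem].format(
            file=p.artifact_file, name=p.name, env_path=env_path
        )
        lines += [
            f'if [ ! -e "{marker}" ]; then',
            f"  {cmd}",
            f'  touch "{marker}"',
            "fi",
        ]
    lines.append("exit 0")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# capture

def capture_install(
    requests: Sequence[PackageRequest],
    backend: SandboxBackend,
    registry: Registry,
    base_image_ref: str = DEFAULT_BASE_IMAGE,
) -> tuple[CaptureManifest, dict[str, bytes]]:
    """Run phase 1: fetch the closure in a disposable sandbox.

    Returns the manifest plus the collected artifact contents keyed by
    filename.  The sandbox session is destroyed in all cases; on backend
    failure a :class:`BackendError` carrying the partial log is raised and
    nothing is returned or written.
    """
    order = resolve_dependencies(requests, registry)
    session = backend.start(base_image_ref)
    log_parts: list[str] = []
    try:
        for pkg in order:
            cmd = f"fetch {pkg.ecosystem} {pkg.name} {pkg.version}"
            code, log = backend.run(session, cmd)
            log_parts.append(log)
            if code != 0:
                raise BackendError(
                    f"sandbox command failed ({cmd!r}, exit {code})",
                    log="\n".join(log_parts),
                )
        files = backend.collect_files(session, "/capture/artifacts")
    finally:
        backend.destroy(session)

    packages: list[ResolvedPackage] = []
    for pkg in order:
        fname, _ = registry.artifact(pkg.name, pkg.ecosystem, pkg.version)
        if fname not in files:
            raise BackendError(f"artifact not collected from sandbox: {fname}")
        content = files[fname]
        packages.append(
            replace(
                pkg,
                artifact_file=fname,
                byte_size=len(content),
                checksum=hashlib.sha256(content).hexdigest(),
            )
        )
    env_specs = [
        EnvSpec(env_name=req.name, kind=req.ecosystem)
        for req in requests
        if req.ecosystem in ("conda", "bioconda")
    ]
    manifest = CaptureManifest(
        packages=packages,
        env_specs=env_specs,
        base_image_ref=base_image_ref,
        created_at=datetime.now(timezone.utc).isoformat(),
    )
    manifest.install_script = generate_offline_install_script(
        manifest, available_files=files.keys()
    )
    artifact_contents = {p.artifact_file: files[p.artifact_file] for p in packages}
    return manifest, artifact_contents


def save_capture(
    manifest: CaptureManifest, files: dict[str, bytes], outdir: str
) -> None:
    """Write the capture directory layout: artifacts/, manifest.json, install_offline.sh."""
    art_dir = os.path.join(outdir, "artifacts")
    os.makedirs(art_dir, exist_ok=True)
    for fname, content in files.items():
        with open(os.path.join(art_dir, fname), "wb") as fh:
            fh.write(content)
    with open(os.path.join(outdir, "manifest.json"), "w", newline="\n") as fh:
        fh.write(manifest.to_json(include_timestamp=True))
    with open(os.path.join(outdir, "install_offline.sh"), "w", newline="\n") as fh:
        fh.write(manifest.install_script)
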