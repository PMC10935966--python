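"""Domain model: ecosystems, package requests, layers, build plans.

The generator composes an image out of numbered *layers*:

====  ==================  =========================================
 #    canonical slug      contents
====  ==================  =========================================
 0    PythonPackages /    one language stack (Python or R) with its
      RPackages           captured package set
 1    mergeDocker         merge of the two layer-0 stacks
 2    GUI                 one web IDE served on container port 8888
 3    VMInDocker          nested docker/singularity runtime
 4    ExternalSoftware    OS packages (apt ecosystem)
====  ==================  =========================================

Every layer's output lives in a folder named ``<number>_<slug>``.  In
*strict* mode (the GUI semantics) selecting layer N requires every layer
below N; *permissive* mode (engine semantics) allows any subset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import ForgeError

#: Repository families a package request may come from.
ECOSYSTEMS: frozenset[str] = frozenset(
    {
        "pypi-like",
        "cran-like",
        "bioconductor-like",
        "conda",
        "bioconda",
        "source-host",
        "apt",
    }
)

GUI_CHOICES: tuple[str, ...] = ("jupyterlab", "jupyternotebook", "rstudio", "visualstudio")
VM_CHOICES: tuple[str, ...] = ("docker", "singularity")
LANGUAGE_CHOICES: tuple[str, ...] = ("python-stack", "r-stack")

#: Canonical folder slugs for the built-in layers (layer 0 depends on the
#: chosen language, see :func:`default_slug`).
CANONICAL_SLUGS: dict[int, str] = {
    1: "mergeDocker",
    2: "GUI",
    3: "VMInDocker",
    4: "ExternalSoftware",
}

_IMAGE_NAME_RE = re.compile(r"^[a-z]{1,128}$")
_FOLDER_RE = re.compile(r"^(\d+)_(.+)$")


@dataclass(frozen=True)
class PackageRequest:
    """One user-requested package: a name, its ecosystem, an optional pin.

    ``source_ref`` (a repository locator, e.g. an org/repo path) is required
    for the ``source-host`` ecosystem and forbidden elsewhere.
    """

    name: str
    ecosystem: str
    version: Optional[str] = None
    source_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ecosystem not in ECOSYSTEMS:
            raise ForgeError(f"unknown ecosystem: {self.ecosystem!r}")
        if not self.name or any(c.isspace() for c in self.name):
            raise ForgeError(f"invalid package name: {self.name!r}")
        if (self.ecosystem == "source-host") != (self.source_ref is not None):
            raise ForgeError(
                "source_ref must be given exactly when ecosystem is 'source-host' "
                f"(got ecosystem={self.ecosystem!r}, source_ref={self.source_ref!r})"
            )


def default_slug(number: int, options: Mapping[str, str]) -> str:
    """Canonical folder slug for a built-in layer number."""
    if number == 0:
        return "RPackages" if options.get("language") == "r-stack" else "PythonPackages"
    try:
        return CANONICAL_SLUGS[number]
    except KeyError:
        raise ForgeError(f"no canonical slug for layer {number}; supply one explicitly")


@dataclass(frozen=True)
class LayerConfig:
    """One layer of a build plan: its number, folder slug and options.

    Options in use: ``language`` (layer 0), ``gui`` (layer 2), ``vm``
    (layer 3).  Additional layers (number >= 5) may register through the
    same folder convention but must supply their slug explicitly.
    """

    number: int
    slug: str = ""
    options: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.number < 0:
            raise ForgeError(f"layer number must be >= 0, got {self.number}")
        if not self.slug:
            object.__setattr__(self, "slug", default_slug(self.number, self.options))


def layer_folder_name(layer: LayerConfig) -> str:
    """Folder name ``<number>_<slug>`` for a layer.

    Layer-2 folders incorporate the chosen GUI so that the output folder
    self-describes which IDE it provisions.
    """
    if layer.number < 0:
        raise ForgeError(f"invalid layer number {layer.number}")
    slug = layer.slug
    if layer.number == 2 and "gui" in layer.options:
        slug = f"{slug}_{layer.options['gui']}"
    return f"{layer.number}_{slug}"


def parse_layer_folder_name(folder: str) -> tuple[int, str]:
    """Inverse of :func:`layer_folder_name`: ``"0_RPackages" -> (0, "RPackages")``."""
    m = _FOLDER_RE.match(folder)
    if not m:
        raise ForgeError(f"not a layer folder name: {folder!r}")
    return int(m.group(1)), m.group(2)


@dataclass(frozen=True)
class ImageNameVerdict:
    ok: bool
    violations: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # truthiness == validity
        return self.ok


def validate_image_name(name: str) -> ImageNameVerdict:
    """Check an image name against the rule: lowercase ASCII letters only.

    The name must be non-empty, at most 128 characters, and consist solely
    of ``a``–``z`` — no digits, no separators.  Returns a verdict object;
    callers decide whether to raise.
    """
    violations: list[str] = []
    if not name:
        return ImageNameVerdict(False, ("empty name",))
    if len(name) > 128:
        violations.append(f"name longer than 128 characters ({len(name)})")
    if any("A" <= c <= "Z" for c in name):
        violations.append("uppercase letters are not allowed")
    if any(c.isdigit() for c in name):
        violations.append("digits are not allowed")
    if any(not ("a" <= c <= "z" or "A" <= c <= "Z" or c.isdigit()) for c in name):
        violations.append("special characters are not allowed")
    assert _IMAGE_NAME_RE.match(name) is None or not violations
    return ImageNameVerdict(not violations, tuple(violations))


@dataclass(frozen=True)
class BuildPlan:
    """An ordered set of layers plus plan-wide settings.

    ``mode`` is ``"strict"`` (default: layer N requires all layers < N) or
    ``"permissive"`` (any subset).  ``image_name`` is mandatory once layer 2
    is part of the plan; ``host_path`` is where output folders are written.
    """

    layers: Sequence[LayerConfig]
    mode: str = "strict"
    image_name: Optional[str] = None
    host_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "permissive"):
            raise ForgeError(f"mode must be 'strict' or 'permissive', got {self.mode!r}")
        object.__setattr__(self, "layers", tuple(self.layers))

    def layer(self, number: int) -> LayerConfig:
        for lc in self.layers:
            if lc.number == number:
                return lc
        raise KeyError(number)

    @property
    def numbers(self) -> tuple[int, ...]:
        return tuple(lc.number for lc in self.layers)


def validate_layer_plan(plan: BuildPlan) -> list[str]:
    """Validate a plan; return a list of violations (empty == valid).

    Checks the mode's prerequisite rule and per-layer option completeness:
    layer 2 needs exactly one GUI choice and a valid image name, layer 3 a
    nested-VM choice, layer 0 a known language stack.
    """
    violations: list[str] = []
    numbers = [lc.number for lc in plan.layers]
    if not numbers:
        violations.append("plan contains no layers")
        return violations
    seen: set[int] = set()
    for n in numbers:
        if n in seen:
            violations.append(f"layer {n} appears more than once")
        seen.add(n)

    if plan.mode == "strict":
        for n in sorted(seen):
            missing = [m for m in range(n) if m not in seen]
            for m in missing:
                violations.append(f"strict mode: layer {n} requires missing layer {m}")

    for lc in plan.layers:
        if lc.number == 0:
            lang = lc.options.get("language")
            if lang is not None and lang not in LANGUAGE_CHOICES:
                violations.append(f"layer 0: unknown language {lang!r}")
        elif lc.number == 2:
            gui = lc.options.get("gui")
            if gui is None:
                violations.append("layer 2: a GUI choice is required")
            elif "," in gui or gui not in GUI_CHOICES:
                violations.append(f"layer 2: exactly one GUI of {GUI_CHOICES} required, got {gui!r}")
            if plan.image_name is None:
                violations.append("layer 2: an image name is required")
            else:
                verdict = validate_image_name(plan.image_name)
                violations.extend(f"image name: {v}" for v in verdict.violations)
        elif lc.number == 3:
            vm = lc.options.get("vm")
            if vm not in VM_CHOICES:
                violations.append(f"layer 3: vm choice of {VM_CHOICES} required, got {vm!r}")
    return violations
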