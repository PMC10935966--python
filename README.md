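# imageforge

Self-contained, offline-buildable Docker build folders for bioinformatics
environments.

## Why

A Dockerfile that says `pip install scanpy` builds a different image every
time upstream moves: versions drift, links break, packages vanish. For
computational biology — where a library version can change a result — the
honest reproducibility unit is not the recipe but the recipe *plus every
file it installs*.

imageforge implements that as a two-phase procedure:

1. **Assembly.** Resolve every requested package and its dependency
   closure against a registry, fetch all artifacts inside a disposable
   sandbox container (destroyed afterwards), and record a manifest: exact
   versions, SHA-256 checksums, and a deterministic dependency-respecting
   install order.
2. **Offline build.** Emit, per layer, a folder holding the Dockerfile,
   the captured files split into archive volumes each smaller than 25 MB
   (so the folder can be pushed to ordinary code-hosting services), an
   install script that installs only from those files, and `script.sh` /
   `script.cmd` to build and run the image. Rebuilding later needs the
   network for exactly one thing: pulling the digest-pinned base image.

Images compose from numbered layers, each in a folder `<n>_<slug>`:
`0_PythonPackages`/`0_RPackages` (one language stack), `1_mergeDocker`
(both stacks merged), `2_GUI_<choice>` (one web IDE on port 8888),
`3_VMInDocker` (nested docker/singularity), `4_ExternalSoftware`
(OS packages). Offline closure is machine-checked: a scanner rejects any
generated Dockerfile containing a network-fetch instruction beyond the
base-image line.

Supported package ecosystems: `pypi-like`, `cran-like`,
`bioconductor-like`, `conda`, `bioconda`, `source-host`, `apt`.

## Worked example

Capture three packages from a registry snapshot and emit build folders
for layers 0 and 1:

```sh
$ forge capture --config pkgs.txt --ecosystem pypi-like \
      --registry registry.json --out cap
captured 3 packages -> cap

$ forge show --manifest cap/manifest.json
base image: ubuntu@sha256:cb287cf26b15fded26828219b268886d76ea3963bc93495425dcf08225c86e9f
    0  pypi-like:numpy==1.26.4  (2962 B, sha256 04e25928443c...)
    1  pypi-like:pandas==2.2.1  (1410 B, sha256 7d4f84283404...)
    2  pypi-like:scanpy==1.10.0  (2633 B, sha256 70ebc60624e0...)
```

`pkgs.txt` requested only `scanpy,pandas`; `numpy` entered the manifest
as a resolved dependency, ordered before its dependents (install indexes
0–2 form a topological order of the recorded dependency graph). The
checksums let any later rebuild verify the artifacts bit-for-bit.

```sh
$ forge assemble --layer 0 --layer 1 --mode permissive \
      --image-name credimage --host-path out \
      --config 0:pkgs.txt --registry registry.json --seed 1
0_PythonPackages
1_mergeDocker

$ forge scan out/0_PythonPackages/Dockerfile
offline-closed: no network references beyond the base image
```

Each emitted folder contains the Dockerfile, the chunked volumes
(`layerdata.part0000`, …) with their manifest, `manifest.json`,
`install_offline.sh`, both run scripts and a build log. The install
script installs strictly in resolved order, offline:

```sh
$ head -6 out/0_PythonPackages/install_offline.sh
#!/bin/sh
# generated offline install script -- installs from ./artifacts only
set -e
mkdir -p /var/lib/forge/installed
if [ ! -e "/var/lib/forge/installed/pypi-like__numpy__1.26.4" ]; then
  python -m pip install --no-index --no-deps ./artifacts/numpy-1.26.4.whl
```

Running `out/0_PythonPackages/script.sh` on a machine with Docker builds
the image (`--platform linux/amd64` pinned), mounts a host directory at
`/sharedFolder`, and attaches a shell; layer-2 scripts instead publish
the GUI on <http://localhost:8888> and detach.

The same operations are available as a library
(`imageforge.capture_install`, `chunk_files`, `build_plan_outputs`,
`scan_offline_closure`, …); the CLI is a thin wrapper.

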