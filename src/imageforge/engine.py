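"""Container-engine sandbox backend (optional).

A thin wrapper that drives a real temporary container through the
``docker`` CLI, satisfying the same :class:`~imageforge.capture.SandboxBackend`
contract as the mock.  It is a convenience for interactive use only: every
test and the whole emission pipeline run against the mock backend, so this
module is never required for correctness.
"""

from __future__ import annotations

import shutil
import subprocess
import uuid

from .errors import BackendError


class EngineSandboxBackend:
    """Run capture commands inside a disposable container via the docker CLI."""

    def __init__(self, docker_bin: str = "docker"):
        if shutil.which(docker_bin) is None:
            raise BackendError(
                f"container engine binary {docker_bin!r} not found on PATH; "
                "use the mock backend for engine-free operation"
            )
        self.docker_bin = docker_bin

    def start(self, base_image_ref: str) -> str:
        name = f"forge-capture-{uuid.uuid4().hex[:12]}"
        self._run_cli(
            "run", "--detach", "--name", name, "--platform", "linux/amd64",
            base_image_ref, "sleep", "infinity",
        )
        return name

    def run(self, session: str, command: str) -> tuple[int, str]:
        proc = subprocess.run(
            [self.docker_bin, "exec", session, "sh", "-c", command],
            capture_output=True, text=True,
        )
        return proc.returncode, proc.stdout + proc.stderr

    def collect_files(self, session: str, path: str) -> dict[str, bytes]:
        import io
        import tarfile

        proc = subprocess.run(
            [self.docker_bin, "cp", f"{session}:{path}", "-"], capture_output=True
        )
        if proc.returncode != 0:
            raise BackendError("docker cp failed", log=proc.stderr.decode(errors="replace"))
        files: dict[str, bytes] = {}
        with tarfile.open(fileobj=io.BytesIO(proc.stdout)) as tf:
            for member in tf.getmembers():
                if member.isfile():
                    fh = tf.extractfile(member)
                    files[member.name.rsplit("/", 1)[-1]] = fh.read() if fh else b""
        return files

    def destroy(self, session: str) -> None:
        subprocess.run(
            [self.docker_bin, "rm", "--force", session],
            capture_output=True,
        )

    def _run_cli(self, *args: str) -> str:
        proc = subprocess.run(
            [self.docker_bin, *args], capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise BackendError(
                f"docker {' '.join(args[:2])} failed", log=proc.stdout + proc.stderr
            )
        return proc.stdout
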