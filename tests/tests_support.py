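"""Shared helpers for the test suite."""

from cxrcad.image_io import Manifest, ManifestRecord
from cxrcad.model_zoo import ModelSpec


def synthetic_jsrt_manifest(n_cancer: int = 154, n_normal: int = 93) -> Manifest:
    """A JSRT-shaped manifest (247 records, 154 cancer / 93 normal) with
    synthetic ids and paths, standing in for the real dataset index."""
    records = [
        ManifestRecord(f"JPCLN{k:03d}", f"JPCLN{k:03d}.png", None, "cancer")
        for k in range(1, n_cancer + 1)
    ] + [
        ManifestRecord(f"JPCNN{k:03d}", f"JPCNN{k:03d}.png", None, "normal")
        for k in range(1, n_normal + 1)
    ]
    manifest = Manifest(records)
    manifest.validate()
    return manifest


def independent_parameter_count(spec: ModelSpec) -> int:
    """Arithmetic oracle for the custom CNN's trainable parameters:
    conv k^2*c_in*c_out + c_out; BN 2*c; FC in*out + out."""
    cfg = spec.config
    total, c_in, size = 0, 1, cfg["input_size"]
    for c_out in cfg["block_filters"]:
        total += cfg["kernel"] ** 2 * c_in * c_out + c_out
        total += 2 * c_out
        c_in = c_out
        size = -(-size // cfg["block_stride"])
    size //= 2
    total += size * size * c_in * cfg["fusion_width"] + cfg["fusion_width"]
    total += cfg["fusion_width"] * cfg["n_classes"] + cfg["n_classes"]
    return total
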