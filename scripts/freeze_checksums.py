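"""Regenerate the SHA-256 integrity manifest for packaged data resources."""
import hashlib
import json
import pathlib

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "etrapbpk" / "data"

manifest = {
    p.name: hashlib.sha256(p.read_text().encode()).hexdigest()
    for p in sorted(DATA.iterdir())
    if p.suffix in (".csv", ".yaml") and p.name != "checksums.json"
}
(DATA / "checksums.json").write_text(json.dumps(manifest, indent=1) + "\n")
print(f"froze {len(manifest)} resources")
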