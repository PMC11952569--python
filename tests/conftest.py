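"""Shared pytest configuration.

The brute-force oracles live in tests/oracles.py and are imported directly
by the test modules (pytest puts this directory on sys.path).
"""
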