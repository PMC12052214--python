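# Regenerate all experiment tables (full mode) and the scenario table.
OUT ?= chandelier_out

all:
	chandelier all -o $(OUT)

scaled:
	chandelier all --scaled-down -o $(OUT)

test:
	python -m pytest -q tests/

.PHONY: all scaled test
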