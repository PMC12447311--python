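# Declarative annotation flag rules: <field>	<case-insensitive substring>	<flag>
# field is "keyword" (UniProt keyword list) or "location" (subcellular location text).
# "Membrane protein" is operationalized as: keyword Membrane, or a subcellular
# location naming the cell/plasma membrane. Swap this file to change the rule.
keyword	Membrane	is_membrane
location	Cell membrane	is_membrane
location	Plasma membrane	is_membrane
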