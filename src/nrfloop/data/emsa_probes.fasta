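>query_probe AMPK ARE query oligonucleotide (sense strand)
AAACCATGACTCTGCATAAAA
>consensus_probe AMPK ARE consensus oligonucleotide (sense strand)
AAACCATGACACAGCATAAAA
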