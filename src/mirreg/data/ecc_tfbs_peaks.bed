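chrE	101787	101987	chip_example
chrE	200367	200567	chip_example
chrE	302942	303142	chip_example
chrE	399845	400045	chip_example
chrE	495614	495814	chip_example
chrE	600026	600226	chip_example
chrE	695614	695814	chip_example
chrE	795452	795652	chip_example
chrE	898666	898866	chip_example
chrE	1000832	1001032	chip_example
chrE	1099714	1099914	chip_example
chrE	1201958	1202158	chip_example
chrE	1299895	1300095	chip_example
chrE	1402162	1402362	chip_example
chrE	1501355	1501555	chip_example
chrE	1598183	1598383	chip_example
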