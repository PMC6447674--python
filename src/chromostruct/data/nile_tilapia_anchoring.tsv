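lg	previous_bp	new_bp
LG1	38372991	40673430
LG2	35256741	36523203
LG3	68550753	87567345
LG4	38038224	35549522
LG5	34628617	39714817
LG6	44571662	42433576
LG7	62059223	64772279
LG8	30802437	30527416
LG9	27519051	35850837
LG10	32426571	34704454
LG11	36466354	39275952
LG12	41232431	38600464
LG13	32337344	34734273
LG14	39264731	40509636
LG15	36154882	39688505
LG16	43860769	36041493
LG17	40919683	38839487
LG18	37007722	38636442
LG19	31245232	30963196
LG20	36767035	37140374
LG22	37011614	39199643
LG23	44097196	45655644
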