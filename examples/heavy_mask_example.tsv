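# Illustrative heavy-chain position mask (Kabat-style labels H1..H112,
# insertion codes omitted). NON-AUTHORITATIVE: the exact set of CDR
# positions excluded from scoring is a curation choice that must come
# from the user; this file only demonstrates the two-column format
# (position label, keep flag). Here the central, structurally variable
# stretches of the three CDRs are dropped and their conserved stubs kept.
H1	1
H2	1
H3	1
H4	1
H5	1
H6	1
H7	1
H8	1
H9	1
H10	1
H11	1
H12	1
H13	1
H14	1
H15	1
H16	1
H17	1
H18	1
H19	1
H20	1
H21	1
H22	1
H23	1
H24	1
H25	1
H26	1
H27	1
H28	1
H29	1
H30	1
H31	0
H32	0
H33	0
H34	0
H35	1
H36	1
H37	1
H38	1
H39	1
H40	1
H41	1
H42	1
H43	1
H44	1
H45	1
H46	1
H47	1
H48	1
H49	1
H50	1
H51	1
H52	0
H53	0
H54	0
H55	0
H56	0
H57	1
H58	1
H59	1
H60	1
H61	1
H62	1
H63	1
H64	1
H65	1
H66	1
H67	1
H68	1
H69	1
H70	1
H71	1
H72	1
H73	1
H74	1
H75	1
H76	1
H77	1
H78	1
H79	1
H80	1
H81	1
H82	1
H83	1
H84	1
H85	1
H86	1
H87	1
H88	1
H89	1
H90	1
H91	1
H92	1
H93	1
H94	1
H95	1
H96	0
H97	0
H98	0
H99	0
H100	0
H101	0
H102	1
H103	1
H104	1
H105	1
H106	1
H107	1
H108	1
H109	1
H110	1
H111	1
H112	1
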