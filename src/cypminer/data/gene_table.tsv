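GeneName	Type	CYPClan	CYPFamily	CYPSubfamily	Length	PI	MolWt_kDa	Loc
SmCYP98A75	A	71	CYP98	CYP98A	509	8.96	57.9	S
SmCYP73A120	A	71	CYP73	CYP73A	504	9.11	57.7	S
SmCYP93B25	A	71	CYP93	CYP93B	510	8.59	57.4	unknown
SmCYP98A76	A	71	CYP98	CYP98A	512	8.55	58.0	S
SmCYP98A77	A	71	CYP98	CYP98A	508	8.88	57.2	unknown
SmCYP51G1	non-A	51	CYP51	CYP51G	492	8.09	55.3	S
SmCYP701A40	A	71	CYP701	CYP701A	519	7.22	58.8	S
SmCYP704A98	non-A	86	CYP704	CYP704A	511	6.74	59.2	S
SmCYP704B37	non-A	86	CYP704	CYP704B	506	7.16	58.2	S
SmCYP704A99	non-A	86	CYP704	CYP704A	506	6.9	57.7	S
SmCYP706C35	A	71	CYP706	CYP706C	518	8.17	57.7	unknown
SmCYP706G11	A	71	CYP706	CYP706G	507	9.06	56.8	unknown
SmCYP707A99	non-A	85	CYP707	CYP707A	488	9.27	55.1	S
SmCYP707A100	non-A	85	CYP707	CYP707A	481	9.45	54.9	unknown
SmCYP707A101	non-A	85	CYP707	CYP707A	479	9.34	54.9	S
SmCYP707A102	non-A	85	CYP707	CYP707A	470	8.6	53.0	S
SmCYP711A44	non-A	711	CYP711	CYP711A	514	9.37	57.6	S
SmCYP714A25	non-A	72	CYP714	CYP714A	527	8.64	59.1	S
SmCYP714E21	non-A	72	CYP714	CYP714E	523	8.71	58.5	S
SmCYP716A89	non-A	85	CYP716	CYP716A	479	8.76	54.0	S
SmCYP716C12	non-A	85	CYP716	CYP716C	476	9	53.4	S
SmCYP728D17	non-A	85	CYP728	CYP728D	483	8.9	55.4	S
SmCYP716D25	non-A	85	CYP716	CYP716D	477	9.13	54.3	S
SmCYP71AU51	A	71	CYP71	CYP71AU	505	6.62	56.4	unknown
SmCYP71AU52	A	71	CYP71	CYP71AU	500	6.66	56.4	unknown
SmCYP71AH15	A	71	CYP71	CYP71AH	496	6.05	55.5	S
SmCYP71AP14	A	71	CYP71	CYP71AP	522	6.14	58.7	unknown
SmCYP71A57	A	71	CYP71	CYP71A	497	8.47	55.8	unknown
SmCYP71A58	A	71	CYP71	CYP71A	505	6.33	56.9	S
SmCYP71A59	A	71	CYP71	CYP71A	500	6.27	56.0	unknown
SmCYP71D410	A	71	CYP71	CYP71D	504	7.65	56.5	S
SmCYP71D411	A	71	CYP71	CYP71D	498	7.2	56.6	S
SmCYP71D374	A	71	CYP71	CYP71D	502	8.73	57.1	unknown
SmCYP71BE37	A	71	CYP71	CYP71BE	498	8.34	56.8	unknown
SmCYP71D412	A	71	CYP71	CYP71D	502	6.7	57.2	unknown
SmCYP71D413	A	71	CYP71	CYP71D	511	6.14	58.2	unknown
SmCYP720A1	non-A	85	CYP720	CYP720A	494	8.97	56.5	S
SmCYP72A326	non-A	72	CYP72	CYP72A	518	9.3	59.1	S
SmCYP72A327	non-A	72	CYP72	CYP72A	518	9.04	59.1	S
SmCYP72A328	non-A	72	CYP72	CYP72A	517	9.01	59.6	S
SmCYP72A329	non-A	72	CYP72	CYP72A	512	9.03	58.1	S
SmCYP72A330	non-A	72	CYP72	CYP72A	517	9.1	59.1	S
SmCYP72A331	non-A	72	CYP72	CYP72A	516	8.72	59.0	S
SmCYP734A33	non-A	72	CYP734	CYP734A	522	9.1	59.6	S
SmCYP749A37	non-A	72	CYP749	CYP749A	508	8.95	58.3	S
SmCYP749A38	non-A	72	CYP749	CYP749A	508	9.25	58.4	S
SmCYP721A38	non-A	72	CYP721	CYP721A	506	8.93	58.3	S
SmCYP749A39	non-A	72	CYP749	CYP749A	511	9.14	58.5	S
SmCYP749A40	non-A	72	CYP749	CYP749A	509	9	57.9	S
SmCYP727B10	non-A	727	CYP727	CYP727B	502	8.59	56.4	S
SmCYP714G13	non-A	72	CYP714	CYP714G	506	9.34	56.4	S
SmCYP714G14	non-A	72	CYP714	CYP714G	514	9.16	57.5	S
SmCYP736A121	A	71	CYP736	CYP736A	496	6.72	56.4	unknown
SmCYP736A122	A	71	CYP736	CYP736A	502	6.82	57.1	unknown
SmCYP736A123	A	71	CYP736	CYP736A	488	7.07	55.3	unknown
SmCYP74A1	non-A	74	CYP74	CYP74A	519	8.88	58.0	C
SmCYP74B21	non-A	74	CYP74	CYP74B	483	5.91	53.9	unknown
SmCYP75B79	A	71	CYP75	CYP75B	511	7.73	56.2	unknown
SmCYP75B80	A	71	CYP75	CYP75B	514	7.3	56.5	unknown
SmCYP92B28	A	71	CYP92	CYP92B	501	6.55	56.5	S
SmCYP75A57	A	71	CYP75	CYP75A	516	8.43	57.6	S
SmCYP92A73	A	71	CYP92	CYP92A	509	8.93	57.9	unknown
SmCYP92B29	A	71	CYP92	CYP92B	509	6.69	57.7	unknown
SmCYP76AH1	A	71	CYP76	CYP76AH	495	7.73	55.5	unknown
SmCYP76AK2	A	71	CYP76	CYP76AK	494	8.72	55.8	unknown
SmCYP76S7	A	71	CYP76	CYP76S	494	7.67	55.8	unknown
SmCYP76AK3	A	71	CYP76	CYP76AK	491	8.85	55.4	unknown
SmCYP76T27	A	71	CYP76	CYP76T	486	8.83	55.0	unknown
SmCYP76A35	A	71	CYP76	CYP76A	503	8.25	57.8	unknown
SmCYP76A36	A	71	CYP76	CYP76A	513	8.9	57.7	unknown
SmCYP77A27	A	71	CYP77	CYP77A	512	9.13	57.6	S
SmCYP77A28	A	71	CYP77	CYP77A	505	9.16	56.8	unknown
SmCYP78A113	A	71	CYP78	CYP78A	511	8.61	57.3	S
SmCYP78A114	A	71	CYP78	CYP78A	533	9.24	59.1	unknown
SmCYP78A115	A	71	CYP78	CYP78A	526	9.1	57.9	S
SmCYP79D40	A	71	CYP79	CYP79D	522	8.98	58.7	S
SmCYP81Q40	A	71	CYP81	CYP81Q	493	7.3	55.8	unknown
SmCYP81B61	A	71	CYP81	CYP81B	510	8.9	58.1	S
SmCYP81B62	A	71	CYP81	CYP81B	498	7.68	55.9	S
SmCYP81Q41	A	71	CYP81	CYP81Q	494	7.68	56.0	unknown
SmCYP81Q42	A	71	CYP81	CYP81Q	493	6.27	56.1	unknown
SmCYP81Q43	A	71	CYP81	CYP81Q	494	7.68	56.0	unknown
SmCYP81C16	A	71	CYP81	CYP81C	498	8.07	55.8	S
SmCYP82V2	A	71	CYP82	CYP82V	534	6.61	60.2	S
SmCYP82D70	A	71	CYP82	CYP82D	516	8.9	57.6	unknown
SmCYP82D71	A	71	CYP82	CYP82D	516	6.59	57.4	S
SmCYP82U4	A	71	CYP82	CYP82U	522	7.71	58.8	S
SmCYP71AT89	A	71	CYP71	CYP71AT	499	8.87	56.1	unknown
SmCYP71AT90	A	71	CYP71	CYP71AT	496	7.69	55.6	unknown
SmCYP71AT91	A	71	CYP71	CYP71AT	506	8.44	56.7	unknown
SmCYP71AT92	A	71	CYP71	CYP71AT	506	6.15	57.4	S
SmCYP71AT93	A	71	CYP71	CYP71AT	491	9.05	55.3	unknown
SmCYP84A60	A	71	CYP84	CYP84A	517	5.68	58.0	S
SmCYP84A61	A	71	CYP84	CYP84A	517	6.61	58.0	S
SmCYP85A1	non-A	85	CYP85	CYP85A	463	8.88	53.3	S
SmCYP86A91	non-A	86	CYP86	CYP86A	555	8.48	62.3	S
SmCYP86A92	non-A	86	CYP86	CYP86A	525	8.28	59.6	S
SmCYP96A84	non-A	86	CYP96	CYP96A	485	8.96	55.0	S
SmCYP96A85	non-A	86	CYP96	CYP96A	502	8.42	57.8	unknown
SmCYP88A52	non-A	85	CYP88	CYP88A	487	9.26	56.2	S
SmCYP89A115	A	71	CYP89	CYP89A	500	7.66	57.7	S
SmCYP90A39	non-A	85	CYP90	CYP90A	478	9.12	54.4	unknown
SmCYP90B26	non-A	85	CYP90	CYP90B	476	9.05	53.9	S
SmCYP90C19	non-A	85	CYP90	CYP90C	488	8.4	55.5	S
SmCYP94A48	non-A	86	CYP94	CYP94A	502	8.85	57.7	S
SmCYP94A49	non-A	86	CYP94	CYP94A	502	8.6	57.1	S
SmCYP94B50	non-A	86	CYP94	CYP94B	505	8.89	56.1	S
SmCYP94C54	non-A	86	CYP94	CYP94C	491	7.63	55.1	S
SmCYP94C55	non-A	86	CYP94	CYP94C	488	8.45	56.2	S
SmCYP94D47	non-A	86	CYP94	CYP94D	501	9.02	57.1	unknown
SmCYP97A41	non-A	97	CYP97	CYP97A	612	5.89	68.6	C
SmCYP97B34	non-A	97	CYP97	CYP97B	582	6.31	65.0	C
SmCYP97C28	non-A	97	CYP97	CYP97C	542	6.12	60.1	C
SmCYP98A78	A	71	CYP98	CYP98A	508	8.48	57.6	S
SmCYP76G16	A	71	CYP76	CYP76G	508	8.5	57.0	unknown
SmCYP71AU53	A	71	CYP71	CYP71AU	498	9.37	56.6	unknown
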